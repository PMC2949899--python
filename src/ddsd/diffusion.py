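"""Diffusion distances from a Gaussian kernel on inner distances.

Landmarks are the nodes of a complete weighted graph with Gaussian
kernel weights

    k(x, y) = exp(-d(x, y)^2 / sigma^2),

where d is the inner distance by default and sigma defaults to the mean
of all pairwise distances ("auto").  Row-normalising K gives the
single-step Markov transition matrix

    p(x, y) = k(x, y) / v(x),      v(x) = sum_y k(x, y),

whose symmetric conjugate p~(x, y) = k(x, y) / sqrt(v(x) v(y)) shares
its spectrum.  With the eigendecomposition p~ = sum_i lambda_i phi_i
phi_i^T (lambda_1 = 1 >= |lambda_2| >= ...), the m-step diffusion map

    Phi_m(x) = (lambda_1^m phi_1(x), lambda_2^m phi_2(x), ...)

embeds the landmarks so that Euclidean distance in the embedding equals
the diffusion distance

    d_m^2(x, y) = sum_z | p~^(m)(x, z) - p~^(m)(y, z) |^2,

the distance between the m-step transition profiles of x and y.  Because
d_m averages over all paths of the random walk rather than following a
single shortest path, it is far less sensitive than the inner distance
to topological changes (surfaces touching during a deformation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .innerdist import PairwiseDistanceMatrix

__all__ = [
    "KernelMatrix",
    "TransitionMatrices",
    "DiffusionEmbedding",
    "gaussian_kernel",
    "transition_matrices",
    "diffusion_embedding",
    "diffusion_distance_matrix",
    "diffusion_distances",
]

#: default diffusion time (random-walk steps)
DEFAULT_M = 50


@dataclass
class KernelMatrix:
    """Gaussian kernel values k(x, y) in (0, 1] with unit diagonal."""

    K: np.ndarray
    sigma: float
    base_metric: str = "inner"

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-12):
            raise ValueError("kernel matrix must be symmetric")
        if (K <= 0).any():
            raise ValueError("Gaussian kernel values must be strictly positive")
        self.K = K

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class TransitionMatrices:
    """Row-stochastic P, its symmetric conjugate P_sym, and row sums v."""

    P: np.ndarray
    P_sym: np.ndarray
    v: np.ndarray


@dataclass
class DiffusionEmbedding:
    """Eigenpairs of the symmetric transition matrix at diffusion time m.

    ``coords[i]`` is Phi_m(q_i): eigenvector components scaled by
    lambda^m, eigenpairs sorted by descending |lambda|.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns phi_i, orthonormal
    m: int
    sigma: float

    @property
    def coords(self) -> np.ndarray:
        """Diffusion-map coordinates Phi_m, one row per landmark."""
        scale = np.power(self.eigenvalues, self.m)
        return self.eigenvectors * scale[None, :]


def gaussian_kernel(
    D: PairwiseDistanceMatrix | np.ndarray, sigma: float | str = "auto"
) -> KernelMatrix:
    """Gaussian kernel K(i, j) = exp(-D(i, j)^2 / sigma^2).

    ``sigma="auto"`` sets sigma to the mean of D over all unordered
    off-diagonal pairs — the average inner distance between all pairs of
    landmarks on the shape.
    """
    if isinstance(D, PairwiseDistanceMatrix):
        base = D.kind
        vals = D.values
    else:
        base = "unknown"
        vals = np.asarray(D, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")

    if isinstance(sigma, str):
        if sigma != "auto":
            raise ValueError(f"unknown sigma mode {sigma!r}")
        iu = np.triu_indices(vals.shape[0], k=1)
        sigma_val = float(vals[iu].mean())
    else:
        sigma_val = float(sigma)
    if sigma_val <= 0:
        raise ValueError("sigma must be positive")

    K = np.exp(-(vals**2) / sigma_val**2)
    return KernelMatrix(K=K, sigma=sigma_val, base_metric=base)


def transition_matrices(K: KernelMatrix) -> TransitionMatrices:
    """Markov normalisation of a kernel matrix.

    P(i, j) = K(i, j) / v(i) is row-stochastic; P_sym(i, j) =
    K(i, j) / sqrt(v(i) v(j)) is its symmetric conjugate
    D^{1/2} P D^{-1/2} with D = diag(v).
    """
    Km = K.K
    v = Km.sum(axis=1)
    if (v <= 0).any():
        raise ValueError("zero row sum in kernel matrix")
    P = Km / v[:, None]
    P_sym = Km / np.sqrt(np.outer(v, v))
    return TransitionMatrices(P=P, P_sym=P_sym, v=v)


def diffusion_embedding(T: TransitionMatrices, m: int = DEFAULT_M) -> DiffusionEmbedding:
    """Full eigendecomposition of P_sym giving the m-step diffusion map.

    Eigenpairs are sorted by descending |lambda|; each eigenvector's sign
    is fixed so its largest-magnitude component is positive (distances
    are sign-invariant, fixed signs make serialisation reproducible).
    All n eigenpairs are retained.
    """
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError("diffusion time m must be a positive integer")
    w, V = eigh(T.P_sym)  # ascending eigenvalues, orthonormal columns
    order = np.argsort(-np.abs(w), kind="stable")
    w, V = w[order], V[:, order]
    # sign convention: largest-|component| entry of each eigenvector positive
    peak = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[peak, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs[None, :]
    return DiffusionEmbedding(eigenvalues=w, eigenvectors=V, m=int(m), sigma=np.nan)


def diffusion_distance_matrix(E: DiffusionEmbedding) -> PairwiseDistanceMatrix:
    """Pairwise Euclidean distances in the diffusion-map embedding.

    By the spectral identity this equals the diffusion distance d_m
    computed directly from the m-step transition profiles.
    """
    D = squareform(pdist(E.coords))
    return PairwiseDistanceMatrix(values=D, kind="diffusion")


def diffusion_distances(
    D: PairwiseDistanceMatrix | np.ndarray,
    sigma: float | str = "auto",
    m: int = DEFAULT_M,
) -> tuple[PairwiseDistanceMatrix, DiffusionEmbedding]:
    """Distance matrix -> kernel -> Markov chain -> diffusion distances.

    Convenience composition of the individual steps; returns the
    diffusion-distance matrix together with the embedding.
    """
    K = gaussian_kernel(D, sigma=sigma)
    T = transition_matrices(K)
    E = diffusion_embedding(T, m=m)
    E.sigma = K.sigma
    return diffusion_distance_matrix(E), E
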