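"""Landmark selection on the boundary surface.

The descriptor pipeline works on n landmark points S = {q_1, ..., q_n}
chosen from the boundary voxels.  The default scheme runs Lloyd's
k-means (k = n) on the boundary world coordinates and snaps each
centroid to its nearest boundary point, which spreads landmarks close
to uniformly over the surface.  Plain random sampling without
replacement is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .voxel import BoundaryPointSet

__all__ = ["SamplePointSet", "sample_uniform", "sample_random"]


@dataclass
class SamplePointSet:
    """Ordered landmark set on the boundary surface.

    ``source_indices`` are positions into the lexicographically ordered
    boundary point set; ``points`` the matching world coordinates.
    """

    points: np.ndarray
    source_indices: np.ndarray
    n: int
    seed: int
    method: str = "lloyd"

    def __post_init__(self) -> None:
        if len(np.unique(self.source_indices)) != self.n:
            raise ValueError("sample contains duplicate boundary points")


def _check_args(boundary: BoundaryPointSet, n: int) -> None:
    if n < 2:
        raise ValueError("need at least 2 sample points")
    if n > len(boundary):
        raise ValueError(
            f"requested {n} samples but the boundary has only "
            f"{len(boundary)} points"
        )


def sample_uniform(boundary: BoundaryPointSet, n: int, seed: int = 0) -> SamplePointSet:
    """Uniform landmark sampling via Lloyd's k-means on boundary coordinates.

    Runs seeded k-means with k = n (k-means++ initialisation, max 300
    iterations, relative tolerance 1e-4), then snaps each centroid to the
    nearest not-yet-used boundary point, ties broken by lexicographic
    index.  Deterministic given ``seed``.
    """
    _check_args(boundary, n)
    pts = boundary.points
    if n == len(boundary):
        idx = np.arange(n)
        return SamplePointSet(points=pts[idx], source_indices=idx, n=n, seed=seed)

    from sklearn.cluster import KMeans

    km = KMeans(
        n_clusters=n,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=int(seed) % (2**31),
    ).fit(pts)

    # snap each centroid to its nearest unused boundary point; boundary is
    # lexicographically ordered so argmin's first-occurrence rule breaks ties
    d2 = cdist(km.cluster_centers_, pts, metric="sqeuclidean")
    chosen = np.full(n, -1, dtype=np.int64)
    used = np.zeros(len(pts), dtype=bool)
    for c in range(n):
        row = np.where(used, np.inf, d2[c])
        best = int(np.argmin(row))
        chosen[c] = best
        used[best] = True
    return SamplePointSet(points=pts[chosen], source_indices=chosen, n=n, seed=seed)


def sample_random(boundary: BoundaryPointSet, n: int, seed: int = 0) -> SamplePointSet:
    """Random landmark sampling without replacement (baseline scheme)."""
    _check_args(boundary, n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(boundary), size=n, replace=False)
    return SamplePointSet(
        points=boundary.points[idx],
        source_indices=idx,
        n=n,
        seed=seed,
        method="random",
    )
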