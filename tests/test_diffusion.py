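"""Gaussian kernels, Markov normalisation and diffusion embeddings."""

import numpy as np
import pytest

from ddsd.diffusion import (
    diffusion_distance_matrix,
    diffusion_distances,
    diffusion_embedding,
    gaussian_kernel,
    transition_matrices,
)
from ddsd.innerdist import PairwiseDistanceMatrix


def random_distance_matrix(rng: np.random.Generator, n: int) -> PairwiseDistanceMatrix:
    pts = rng.normal(size=(n, 3)) * rng.uniform(1, 10)
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return PairwiseDistanceMatrix(values=D, kind="inner")


def diffusion_distance_by_matrix_power(P_sym: np.ndarray, m: int) -> np.ndarray:
    """Independent oracle: d_m^2(x, y) = sum_z |p~^(m)(x,z) - p~^(m)(y,z)|^2
    with p~^(m) computed by literal m-fold matrix multiplication."""
    Pm = np.linalg.matrix_power(P_sym, m)
    diff = Pm[:, None, :] - Pm[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


class TestGaussianKernel:
    def test_zero_distance_gives_unit_kernel(self):
        D = PairwiseDistanceMatrix(values=np.zeros((3, 3)), kind="inner")
        K = gaussian_kernel(D, sigma=2.0)
        assert (K.K == 1.0).all()

    def test_distance_equal_sigma_gives_exp_minus_one(self):
        D = PairwiseDistanceMatrix(
            values=np.array([[0.0, 2.0], [2.0, 0.0]]), kind="inner"
        )
        K = gaussian_kernel(D, sigma=2.0)
        assert K.K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_auto_sigma_and_kernel_values_hand_computed(self):
        # off-diagonal distances {1, 2, 1}; mean = 4/3
        D = PairwiseDistanceMatrix(
            values=np.array([[0.0, 1, 2], [1, 0.0, 1], [2, 1, 0.0]]), kind="inner"
        )
        K = gaussian_kernel(D, sigma="auto")
        sigma = (1 + 2 + 1) / 3
        assert K.sigma == pytest.approx(sigma)
        assert K.K[0, 1] == pytest.approx(np.exp(-1 / sigma**2))
        assert K.K[0, 2] == pytest.approx(np.exp(-4 / sigma**2))

    def test_nonpositive_sigma_rejected(self):
        D = PairwiseDistanceMatrix(values=np.zeros((2, 2)), kind="inner")
        with pytest.raises(ValueError, match="positive"):
            gaussian_kernel(D, sigma=0.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gaussian_kernel(np.array([[0.0, 1.0], [2.0, 0.0]]), sigma=1.0)


class TestTransitionMatrices:
    def test_uniform_two_point_kernel(self):
        D = PairwiseDistanceMatrix(values=np.zeros((2, 2)), kind="inner")
        T = transition_matrices(gaussian_kernel(D, sigma=1.0))
        np.testing.assert_allclose(T.v, [2.0, 2.0])
        np.testing.assert_allclose(T.P, [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(T.P_sym, T.P)

    def test_rows_of_P_sum_to_one(self):
        rng = np.random.default_rng(1)
        T = transition_matrices(gaussian_kernel(random_distance_matrix(rng, 15)))
        np.testing.assert_allclose(T.P.sum(axis=1), 1.0, atol=1e-12)

    def test_conjugacy_identity(self):
        """P_sym equals D^{1/2} P D^{-1/2} elementwise."""
        rng = np.random.default_rng(2)
        T = transition_matrices(gaussian_kernel(random_distance_matrix(rng, 5)))
        Dh = np.diag(np.sqrt(T.v))
        Dhi = np.diag(1.0 / np.sqrt(T.v))
        np.testing.assert_allclose(T.P_sym, Dh @ T.P @ Dhi, atol=1e-12)


class TestDiffusionEmbedding:
    def test_uniform_two_point_kernel_spectrum(self):
        # eigendecomposition of [[.5,.5],[.5,.5]] is {1, 0}
        D = PairwiseDistanceMatrix(values=np.zeros((2, 2)), kind="inner")
        T = transition_matrices(gaussian_kernel(D, sigma=1.0))
        E = diffusion_embedding(T, m=3)
        np.testing.assert_allclose(E.eigenvalues, [1.0, 0.0], atol=1e-12)
        Dm = diffusion_distance_matrix(E)
        np.testing.assert_allclose(Dm.values, 0.0, atol=1e-12)

    def test_top_eigenvalue_is_one_and_spectrum_bounded(self):
        rng = np.random.default_rng(3)
        T = transition_matrices(gaussian_kernel(random_distance_matrix(rng, 20)))
        E = diffusion_embedding(T, m=1)
        assert E.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert (np.abs(E.eigenvalues) <= 1 + 1e-10).all()

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(4)
        T = transition_matrices(gaussian_kernel(random_distance_matrix(rng, 12)))
        E = diffusion_embedding(T, m=1)
        np.testing.assert_allclose(
            E.eigenvectors.T @ E.eigenvectors, np.eye(12), atol=1e-8
        )

    def test_sign_flip_leaves_distances_unchanged(self):
        rng = np.random.default_rng(5)
        T = transition_matrices(gaussian_kernel(random_distance_matrix(rng, 8)))
        E = diffusion_embedding(T, m=2)
        ref = diffusion_distance_matrix(E).values
        E.eigenvectors = E.eigenvectors * -1.0
        np.testing.assert_allclose(diffusion_distance_matrix(E).values, ref, atol=1e-12)

    def test_invalid_m_rejected(self):
        rng = np.random.default_rng(6)
        T = transition_matrices(gaussian_kernel(random_distance_matrix(rng, 4)))
        for bad in (0, -1, 2.5):
            with pytest.raises(ValueError, match="positive integer"):
                diffusion_embedding(T, m=bad)


class TestDiffusionDistances:
    @pytest.mark.parametrize("m", [1, 5, 50])
    def test_embedding_matches_matrix_power_oracle(self, m):
        """Master test: the spectral embedding reproduces the transition-
        profile distance computed by literal m-fold multiplication."""
        rng = np.random.default_rng(10 + m)
        D = random_distance_matrix(rng, 6)
        T = transition_matrices(gaussian_kernel(D))
        E = diffusion_embedding(T, m=m)
        ref = diffusion_distance_by_matrix_power(T.P_sym, m)
        np.testing.assert_allclose(
            diffusion_distance_matrix(E).values, ref, atol=1e-10
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        D = random_distance_matrix(rng, 10)
        Dm, _ = diffusion_distances(D, m=5)
        perm = rng.permutation(10)
        Dp = PairwiseDistanceMatrix(values=D.values[np.ix_(perm, perm)], kind="inner")
        Dmp, _ = diffusion_distances(Dp, m=5)
        np.testing.assert_allclose(Dmp.values, Dm.values[np.ix_(perm, perm)], atol=1e-9)

    def test_joint_scaling_of_distances_and_sigma_is_neutral(self):
        rng = np.random.default_rng(8)
        D = random_distance_matrix(rng, 12)
        Dm, emb = diffusion_distances(D, sigma=3.0, m=5)
        scaled = PairwiseDistanceMatrix(values=D.values * 7.0, kind="inner")
        Dm2, _ = diffusion_distances(scaled, sigma=21.0, m=5)
        np.testing.assert_allclose(Dm2.values, Dm.values, atol=1e-10)

    def test_total_distance_nonincreasing_in_m(self):
        rng = np.random.default_rng(9)
        D = random_distance_matrix(rng, 15)
        T = transition_matrices(gaussian_kernel(D))
        totals = []
        for m in (1, 2, 5, 10, 50):
            E = diffusion_embedding(T, m=m)
            totals.append(diffusion_distance_matrix(E).values.sum())
        assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_diffusion_distance_is_a_metric(self):
        rng = np.random.default_rng(11)
        D = random_distance_matrix(rng, 20)
        Dm, _ = diffusion_distances(D, m=5)
        v = Dm.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        for _ in range(200):
            i, j, k = rng.integers(0, 20, size=3)
            assert v[i, j] <= v[i, k] + v[k, j] + 1e-10
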