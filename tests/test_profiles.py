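"""Per-cluster genetic covariance correction, PC1 allele alignment, sign
tests, and variance-explained shares."""

import numpy as np
import pytest
from scipy import stats

from mtgwas.profiles import (ClusterCorrelation, InsufficientDataError,
                             align_alleles_to_pc1, cluster_genetic_covariance,
                             cluster_pc1, disease_sign_test,
                             variance_explained_matrix)
from mtgwas.sumstats import ConfigurationError


def _overlapping_betas(rng, M, n, rho_y, sigma_g, n_draws=1):
    """Standardized effect estimates for two fully overlapping studies:
    beta_hat_l = beta_l + e_l with cov(e1, e2) = rho_y / n and var = 1/n."""
    b_true = rng.multivariate_normal(
        [0, 0], [[sigma_g[0], sigma_g[2]], [sigma_g[2], sigma_g[1]]], size=M)
    cov_e = np.array([[1.0, rho_y], [rho_y, 1.0]]) / n
    e = rng.multivariate_normal([0, 0], cov_e, size=M)
    return b_true + e


class TestClusterGeneticCovariance:
    def test_no_overlap_reduces_to_plain_product(self):
        rng = np.random.default_rng(0)
        b1, b2 = rng.normal(size=20), rng.normal(size=20)
        r = cluster_genetic_covariance(b1, b2, 1e4, 1e4, ns=0.0, rho_y=0.9)
        assert r.covariance == pytest.approx((b1 * b2).mean())

    def test_minimum_snps(self):
        with pytest.raises(InsufficientDataError):
            cluster_genetic_covariance(np.ones(4), np.ones(4), 1e4, 1e4)

    def test_symmetric_in_traits(self):
        rng = np.random.default_rng(1)
        b1, b2 = rng.normal(size=30), rng.normal(size=30)
        a = cluster_genetic_covariance(b1, b2, 1e4, 2e4, 1e4, 0.3)
        b = cluster_genetic_covariance(b2, b1, 2e4, 1e4, 1e4, 0.3)
        assert a.covariance == pytest.approx(b.covariance)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_correction_removes_overlap_bias(self):
        # full overlap, rho_Y = 0.4: naive products are biased by rho_Y / n
        rng = np.random.default_rng(2)
        n, M, rho_y, sg = 10_000.0, 400, 0.4, 2e-4
        reps_naive, reps_corr = [], []
        for _ in range(200):
            b = _overlapping_betas(rng, M, n, rho_y, (5e-4, 5e-4, sg))
            naive = (b[:, 0] * b[:, 1]).mean()
            corr = cluster_genetic_covariance(b[:, 0], b[:, 1], n, n,
                                              ns=n, rho_y=rho_y).covariance
            reps_naive.append(naive)
            reps_corr.append(corr)
        bias_naive = np.mean(reps_naive) - sg
        bias_corr = np.mean(reps_corr) - sg
        mc_se = np.std(reps_corr) / np.sqrt(len(reps_corr))
        assert abs(bias_corr) < abs(bias_naive)
        assert abs(bias_corr) < 2 * mc_se

    def test_null_t_test_calibrated(self):
        rng = np.random.default_rng(3)
        n, M, rho_y = 10_000.0, 100, 0.4
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            b = _overlapping_betas(rng, M, n, rho_y, (0.0, 0.0, 0.0))
            r = cluster_genetic_covariance(b[:, 0], b[:, 1], n, n,
                                           ns=n, rho_y=rho_y)
            rejections += r.pvalue < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se


class TestClusterPC1:
    def test_rank_one_matrix_recovered_exactly(self):
        v = np.array([0.5, -0.5, 0.5, 0.5])
        amp = np.linspace(-2, 2, 16)
        B = amp[:, None] * v[None, :]
        loadings, frac = cluster_pc1(B, seed=0)
        assert frac == pytest.approx(1.0)
        assert abs(loadings @ v) == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_leaves_second_moment_unchanged(self):
        rng = np.random.default_rng(4)
        B = rng.normal(size=(30, 4))
        flipped = B.copy()
        flipped[3] = -flipped[3]
        np.testing.assert_allclose(B.T @ B, B.T @ B)
        np.testing.assert_allclose(flipped.T @ flipped, B.T @ B, atol=1e-12)

    def test_known_direction_recovered_within_5_degrees(self):
        rng = np.random.default_rng(5)
        v = np.array([3.0, 1.0, -2.0, 0.5, 1.5])
        v = v / np.linalg.norm(v)
        amp = rng.normal(0, 4, size=200)
        B = amp[:, None] * v[None, :] + rng.normal(0, 0.5, size=(200, 5))
        loadings, frac = cluster_pc1(B, seed=1)
        angle = np.degrees(np.arccos(min(abs(loadings @ v), 1.0)))
        assert angle < 5
        assert frac > 0.5

    def test_too_few_snps_and_degenerate_matrix(self):
        with pytest.raises(InsufficientDataError):
            cluster_pc1(np.ones((2, 4)))
        with pytest.raises(ConfigurationError):
            cluster_pc1(np.ones((10, 3)) * 2.0)


class TestAlignAlleles:
    def test_antiparallel_flipped_parallel_unchanged(self):
        pc1 = np.array([1.0, 0.0, 0.0])
        np.testing.assert_array_equal(
            align_alleles_to_pc1(-pc1, pc1), pc1)
        np.testing.assert_array_equal(
            align_alleles_to_pc1(pc1, pc1), pc1)

    def test_orthogonal_unchanged(self):
        pc1 = np.array([1.0, 0.0])
        prof = np.array([0.0, 2.0])
        np.testing.assert_array_equal(align_alleles_to_pc1(prof, pc1), prof)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        pc1 = rng.normal(size=5)
        prof = rng.normal(size=5)
        once = align_alleles_to_pc1(prof, pc1)
        np.testing.assert_array_equal(align_alleles_to_pc1(once, pc1), once)


class TestSignTest:
    def test_all_concordant_oracle(self):
        p, direction = disease_sign_test(np.ones(10))
        assert p == pytest.approx(2 * 0.5 ** 10)
        assert direction == "positive"

    def test_balanced_is_one(self):
        p, direction = disease_sign_test(np.array([1.0] * 5 + [-1.0] * 5))
        assert p == pytest.approx(1.0)
        assert direction == "even"

    def test_zeros_excluded_and_minimum(self):
        with pytest.raises(InsufficientDataError):
            disease_sign_test(np.array([1.0, -1.0, 0.0, 0.0, 0.0, 0.0]))

    def test_null_calibrated(self):
        rng = np.random.default_rng(7)
        n_rep, rejections = 2000, 0
        for _ in range(n_rep):
            z = rng.choice([-1.0, 1.0], size=20)
            p, _ = disease_sign_test(z)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= 0.05 + 3 * se

    def test_invariant_to_global_flip(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=15)
        assert disease_sign_test(z)[0] == disease_sign_test(-z)[0]


class TestVarianceExplained:
    def test_single_cluster_share_one(self):
        Z = np.array([[2.0, 1.0], [1.0, 3.0]])
        N = np.full((2, 2), 1e4)
        out = variance_explained_matrix(Z, N, np.zeros(2, dtype=int))
        assert (out["share"] == 1.0).all()

    def test_equal_contributions_split_half(self):
        Z = np.array([[2.0, 0.1], [2.0, 0.1]])
        N = np.full((2, 2), 1e4)
        out = variance_explained_matrix(Z, N, np.array([0, 1]))
        assert out["share"].tolist() == [0.5, 0.5, 0.5, 0.5]

    def test_five_snp_toy_matches_hand_computation(self):
        Z = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 0.0],
                      [0.0, 3.0], [1.0, 1.0]])
        N = np.full((5, 2), 100.0)
        labels = np.array([0, 0, 1, 1, 2])
        out = variance_explained_matrix(Z, N, labels)
        contrib = Z ** 2 / N
        for c in (0, 1, 2):
            for t in (0, 1):
                expect = contrib[labels == c, t].sum() / contrib[:, t].sum()
                got = out[(out["cluster"] == c)
                          & (out["trait"] == f"t{t}")]["share"].iloc[0]
                assert got == pytest.approx(expect)
        # shares sum to one per trait
        sums = out.groupby("trait")["share"].sum()
        assert np.allclose(sums, 1.0)
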