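"""Null covariance estimators and the pseudo-inverse machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mtgwas.association import omnibus_scan
from mtgwas.covariance import (ConfigurationError, EstimationError,
                               NullCovariance, SingularityError,
                               empirical_sigma_r, ldsc_sigma, pseudo_inverse,
                               theoretical_sigma_r)
from mtgwas.simulate import (overlap_sigma_r, random_correlation,
                             simulate_ldsc_panel, simulate_null_panel)
from mtgwas.sumstats import SumstatsPanel
import pandas as pd


def _panel_from_z(Z, n=50_000.0):
    m, K = Z.shape
    snps = pd.DataFrame({"snp_id": [f"s{i}" for i in range(m)], "chrom": "1",
                         "pos": np.arange(1, m + 1), "coded_allele": "A",
                         "other_allele": "G"})
    N = np.full_like(Z, n)
    return SumstatsPanel(snps, [f"t{j}" for j in range(K)], Z, N)


class TestTheoretical:
    @pytest.mark.parametrize("n1,n2,ns,rho,expected", [
        (1000, 1000, 1000, 0.5, 0.5),     # complete overlap collapses to rho
        (1000, 2000, 0, 0.9, 0.0),        # independent studies
        (40_000, 10_000, 10_000, 0.4, 0.2),
    ])
    def test_formula(self, n1, n2, ns, rho, expected):
        assert theoretical_sigma_r(n1, n2, ns, rho) == pytest.approx(expected)

    def test_overlap_domain_error(self):
        with pytest.raises(ConfigurationError):
            theoretical_sigma_r(100, 100, 200, 0.5)

    @given(rho=st.floats(-1, 1), ns=st.floats(0, 1000),
           n1=st.floats(1000, 1e6), n2=st.floats(1000, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_bilinear_and_symmetric(self, rho, ns, n1, n2):
        v = theoretical_sigma_r(n1, n2, ns, rho)
        assert v == pytest.approx(rho * ns / np.sqrt(n1 * n2))
        assert theoretical_sigma_r(n2, n1, ns, rho) == pytest.approx(v)
        if -0.5 <= rho <= 0.5:
            assert theoretical_sigma_r(n1, n2, ns, 2 * rho) == pytest.approx(2 * v)


class TestEmpirical:
    def test_naive_recovers_truth_on_null(self):
        rho = random_correlation(4, 3)
        s = overlap_sigma_r(rho, 0.6)
        Z = simulate_null_panel(s, 100_000, 4)
        cov = empirical_sigma_r(_panel_from_z(Z), mode="naive")
        assert np.abs(cov.sigma_r - s).max() < 0.02

    def test_estimators_agree_on_null(self):
        s = overlap_sigma_r(random_correlation(3, 5), 0.5)
        Z = simulate_null_panel(s, 50_000, 6)
        p = _panel_from_z(Z)
        naive = empirical_sigma_r(p, "naive").sigma_r
        pruned = empirical_sigma_r(p, "pruned", subsample=20_000).sigma_r
        trimmed = empirical_sigma_r(p, "trimmed").sigma_r
        assert np.abs(naive - pruned).max() < 0.03
        assert np.abs(naive - trimmed).max() < 0.01

    def _contaminated_panel(self, seed=9):
        # 10% causal SNPs with positively correlated genetic effects
        K, m = 3, 40_000
        s = np.eye(K)
        rng = np.random.default_rng(seed)
        Z = simulate_null_panel(s, m, rng)
        causal = rng.random(m) < 0.10
        shared = rng.normal(0, 2.0, size=causal.sum())
        Z[causal] += shared[:, None]  # same effect on every trait
        return _panel_from_z(Z), s

    def test_naive_biased_up_by_causal_snps(self):
        panel, s = self._contaminated_panel()
        naive = empirical_sigma_r(panel, "naive")
        off = naive.sigma_r[np.triu_indices(3, 1)]
        assert (off > s[np.triu_indices(3, 1)] + 0.05).all()

    def test_trimmed_less_biased_than_naive(self):
        panel, s = self._contaminated_panel()
        naive = empirical_sigma_r(panel, "naive").sigma_r
        trimmed = empirical_sigma_r(panel, "trimmed", trim_p=5e-8).sigma_r
        i = np.triu_indices(3, 1)
        assert (np.abs(trimmed[i] - s[i]) < np.abs(naive[i] - s[i])).all()

    def test_too_few_rows_is_estimation_error(self):
        Z = np.zeros((50, 2)) + np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(EstimationError):
            empirical_sigma_r(_panel_from_z(Z), "naive")


class TestLDSC:
    def test_intercept_recovers_overlap_covariance(self):
        rho = np.array([[1.0, 0.45], [0.45, 1.0]])
        s = overlap_sigma_r(rho, 1.0)  # complete overlap: intercept = rho
        sg = np.array([[0.4, 0.2], [0.2, 0.4]])
        panel, ell = simulate_ldsc_panel(s, sg, n=30_000, m_snps=40_000, seed=12)
        cov = ldsc_sigma(panel, ell, n_blocks=50)
        err = cov.sigma_r[0, 1] - 0.45
        assert abs(err) < max(3 * cov.se_r[0, 1], 0.03)

    def test_slope_recovers_genetic_covariance(self):
        s = np.eye(3)
        rho_g = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.2], [0.3, 0.2, 1.0]])
        sg = 0.5 * rho_g
        panel, ell = simulate_ldsc_panel(s, sg, n=50_000, m_snps=100_000, seed=13)
        cov = ldsc_sigma(panel, ell, n_blocks=50)
        assert np.abs(cov.sigma_g - sg).max() / 0.5 < 0.15

    def test_intercept_invariant_to_genetic_scale(self):
        s = overlap_sigma_r(np.array([[1.0, 0.3], [0.3, 1.0]]), 1.0)
        icpts = []
        for scale in (0.2, 0.8):
            sg = scale * np.array([[1.0, 0.5], [0.5, 1.0]])
            panel, ell = simulate_ldsc_panel(s, sg, 30_000, 40_000, seed=14)
            icpts.append(ldsc_sigma(panel, ell, n_blocks=40).sigma_r[0, 1])
        assert abs(icpts[0] - icpts[1]) < 0.05

    def test_constant_ld_scores_rejected(self):
        Z = simulate_null_panel(np.eye(2), 5000, 1)
        with pytest.raises(EstimationError):
            ldsc_sigma(_panel_from_z(Z), np.full(5000, 10.0))


class TestPseudoInverse:
    def test_identity_all_strategies(self):
        for strat in ("truncate", "floor", "ridge"):
            pinv = pseudo_inverse(NullCovariance(np.eye(4)), strat, 1e-6)
            np.testing.assert_allclose(pinv.matrix, np.eye(4),
                                       atol=2e-6)  # ridge shifts by epsilon
            assert pinv.df == 4

    def _rank_deficient(self, K=20, rank=10, seed=5):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(K, rank))
        return A @ A.T

    def test_truncate_reports_rank_and_moore_penrose(self):
        s = self._rank_deficient()
        pinv = pseudo_inverse(NullCovariance(s + 1e-12 * np.eye(20)),
                              "truncate", 1e-6)
        assert pinv.df == 10
        np.testing.assert_allclose(s @ pinv.matrix @ s, s, atol=1e-8)

    def test_floor_and_ridge_keep_full_df(self):
        s = self._rank_deficient()
        cov = NullCovariance(s + 1e-12 * np.eye(20))
        assert pseudo_inverse(cov, "floor", 1e-3).df == 20
        assert pseudo_inverse(cov, "ridge", 1e-3).df == 20

    def test_all_truncated_is_singularity_error(self):
        with pytest.raises(SingularityError):
            pseudo_inverse(NullCovariance(1e-9 * np.eye(3)), "truncate", 1e-6)

    def test_truncated_omnibus_calibrated_on_singular_null(self):
        # rank-50 covariance of size 100: p-values stay uniform with df=50
        rng = np.random.default_rng(8)
        A = rng.normal(size=(100, 50))
        s = A @ A.T / 50
        cov = NullCovariance(s + 1e-12 * np.eye(100))
        Z = simulate_null_panel(s, 20_000, 9)
        stat, df, p = omnibus_scan(Z, cov, "truncate", 1e-6)
        assert (df == 50).all()
        lam = np.median(stat) / stats.chi2.median(50)
        assert 0.95 < lam < 1.05
        for alpha in (0.05, 0.01):
            se = np.sqrt(alpha * (1 - alpha) / 20_000)
            assert abs((p < alpha).mean() - alpha) < 3 * se


class TestMisspecification:
    def test_downscaled_sigma_inflates_lambda_gc(self):
        s = overlap_sigma_r(random_correlation(5, 7), 0.8)
        Z = simulate_null_panel(s, 50_000, 10)
        good = omnibus_scan(Z, NullCovariance(s))[0]
        biased = omnibus_scan(Z, NullCovariance(0.8 * s))[0]
        med = stats.chi2.median(5)
        assert 0.95 < np.median(good) / med < 1.05
        assert np.median(biased) / med > 1.05
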