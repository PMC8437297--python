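"""Region minima, novelty classification, greedy clumping, and the selection
of representative SNPs for clustering."""

import numpy as np
import pandas as pd
import pytest

from mtgwas.loci import (Clump, classify_novel, clump, region_minp,
                         select_cluster_snps)
from mtgwas.sumstats import (ConfigurationError, LDPanel, RegionSet,
                             SumstatsPanel)


def _ld_from_matrix(mat, prefix="c"):
    n = mat.shape[0]
    ids = [f"{prefix}{i}" for i in range(n)]
    regions = RegionSet(pd.DataFrame({"chrom": ["1"], "start": [0],
                                      "end": [n * 1000]}))
    snps = pd.DataFrame({"snp_id": ids, "chrom": "1",
                         "pos": np.arange(n) * 10 + 1,
                         "coded_allele": "A", "other_allele": "G"})
    return LDPanel(regions, [ids], [mat], snps), ids


class TestRegionMinP:
    def test_minimum_extracted(self):
        out = region_minp(np.array([0.5, 1e-9, 0.03]),
                          np.array([0.9, 0.2, 0.1]), np.array([0, 0, 0]))
        assert out["min_joint_p"].iloc[0] == 1e-9
        assert out["min_univ_p"].iloc[0] == 0.1

    def test_empty_region_absent(self):
        out = region_minp(np.array([0.5, 0.1]), np.array([0.5, 0.1]),
                          np.array([2, 2]))
        assert out["region"].tolist() == [2]

    def test_snp_outside_regions_raises(self):
        with pytest.raises(ConfigurationError):
            region_minp(np.array([0.5]), np.array([0.5]), np.array([-1]))

    def test_two_region_toy_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        jp, up = rng.random(30), rng.random(30)
        idx = np.repeat([0, 1], 15)
        out = region_minp(jp, up, idx).set_index("region")
        for r in (0, 1):
            assert out.loc[r, "min_joint_p"] == jp[idx == r].min()
            assert out.loc[r, "min_univ_p"] == up[idx == r].min()


class TestClassifyNovel:
    @pytest.mark.parametrize("jp,up,expected", [
        (1e-9, 1e-5, "multitrait_only"),
        (1e-9, 1e-9, "both"),
        (2e-8, 2e-8, "neither"),
        (1e-5, 1e-9, "univariate_only"),
    ])
    def test_rule(self, jp, up, expected):
        df = pd.DataFrame({"region": [0], "min_joint_p": [jp],
                           "min_univ_p": [up]})
        assert classify_novel(df)["novelty"].iloc[0] == expected

    def test_partition_exhaustive_exclusive(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"region": np.arange(200),
                           "min_joint_p": 10 ** -rng.uniform(0, 12, 200),
                           "min_univ_p": 10 ** -rng.uniform(0, 12, 200)})
        out = classify_novel(df)
        assert set(out["novelty"]) <= {"multitrait_only", "univariate_only",
                                       "both", "neither"}
        assert out["novelty"].notna().all()


class TestClump:
    def test_single_clump_high_ld(self):
        mat = np.full((3, 3), 0.9)
        np.fill_diagonal(mat, 1.0)
        ld, ids = _ld_from_matrix(mat)
        out = clump(np.array([1e-10, 1e-9, 1e-9]), ld, ids)
        assert len(out) == 1
        assert out[0].lead == 0
        assert sorted(out[0].members.tolist()) == [0, 1, 2]

    def test_independent_snps_all_lead(self):
        ld, ids = _ld_from_matrix(np.eye(3))
        out = clump(np.array([1e-10, 1e-9, 1e-9]), ld, ids)
        assert [c.lead for c in out] == [0, 1, 2]

    def test_six_snp_toy_matches_greedy_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 6))
        c = A @ A.T
        d = np.sqrt(np.diag(c))
        mat = c / np.outer(d, d)
        np.fill_diagonal(mat, 1.0)
        ld, ids = _ld_from_matrix(mat)
        p = np.array([1e-10, 1e-12, 0.5, 1e-9, 1e-11, 1e-9])
        out = clump(p, ld, ids, p1=1e-8, r2=0.2)
        # brute-force greedy oracle
        r2m = mat ** 2
        absorbed, leads = set(), []
        for i in sorted(range(6), key=lambda i: (p[i], i)):
            if p[i] >= 1e-8 or i in absorbed:
                continue
            leads.append(i)
            absorbed |= {j for j in range(6) if r2m[i, j] >= 0.2}
        assert [cl.lead for cl in out] == leads

    def test_lower_p1_never_more_leads(self):
        rng = np.random.default_rng(9)
        idx = np.arange(30)
        mat = 0.7 ** np.abs(idx[:, None] - idx[None, :])
        ld, ids = _ld_from_matrix(mat)
        p = 10 ** -rng.uniform(0, 12, 30)
        n_prev = None
        for p1 in (1e-4, 1e-6, 1e-8, 1e-10):
            n = len(clump(p, ld, ids, p1=p1))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_leads_pairwise_below_r2(self):
        rng = np.random.default_rng(13)
        idx = np.arange(40)
        mat = 0.9 ** np.abs(idx[:, None] - idx[None, :])
        ld, ids = _ld_from_matrix(mat)
        p = 10 ** -rng.uniform(6, 12, 40)
        out = clump(p, ld, ids, p1=1e-5, r2=0.2)
        leads = [c.lead for c in out]
        for a in leads:
            for b in leads:
                if a != b:
                    assert mat[a, b] ** 2 < 0.2


class TestSelectClusterSNPs:
    def _panel(self, ld, ids, observed_frac):
        n = len(ids)
        K = 5
        Z = np.zeros((n, K))
        for i, frac in enumerate(observed_frac):
            n_miss = round((1 - frac) * K)
            if n_miss:
                Z[i, :n_miss] = np.nan
        snps = ld.snps.copy()
        return SumstatsPanel(snps, [f"t{j}" for j in range(K)], Z,
                             np.ones_like(Z))

    def test_union_rule_and_completeness(self):
        mat = np.full((4, 4), 0.9)
        np.fill_diagonal(mat, 1.0)
        ld, ids = _ld_from_matrix(mat)
        # SNP0: best p but only 40% observed; SNP1: 80% observed
        panel = self._panel(ld, ids, [0.4, 0.8, 1.0, 1.0])
        tracks = {"univ_min": np.array([1.0, 1.0, 1.0, 1.0]),
                  "omnibus": np.array([1e-12, 1e-10, 0.5, 0.9]),
                  "sumz_ica": np.ones(4)}
        reps = select_cluster_snps(panel, tracks, ld)
        assert reps.tolist() == [1]  # runner-up with enough observed values

    def test_clump_with_no_complete_member_dropped(self):
        ld, ids = _ld_from_matrix(np.eye(2))
        panel = self._panel(ld, ids, [0.4, 0.4])
        tracks = {"omnibus": np.array([1e-12, 0.5])}
        reps = select_cluster_snps(panel, tracks, ld)
        assert reps.size == 0

    def test_twenty_snp_toy_matches_enumeration(self):
        rng = np.random.default_rng(3)
        idx = np.arange(20)
        mat = 0.8 ** np.abs(idx[:, None] - idx[None, :])
        ld, ids = _ld_from_matrix(mat)
        panel = self._panel(ld, ids, [1.0] * 20)
        p_omni = 10 ** -rng.uniform(0, 14, 20)
        p_univ = 10 ** -rng.uniform(0, 14, 20)
        tracks = {"univ_min": p_univ, "omnibus": p_omni}
        reps = select_cluster_snps(panel, tracks, ld)
        best = np.minimum(p_omni, p_univ)
        # oracle: greedy clump on the per-SNP best track
        r2m = mat ** 2
        absorbed, expect = set(), []
        for i in sorted(range(20), key=lambda i: (best[i], i)):
            if best[i] >= 1e-8 or i in absorbed:
                continue
            expect.append(i)
            absorbed |= {j for j in range(20) if r2m[i, j] >= 0.2}
        assert reps.tolist() == sorted(expect)
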