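"""Simulation generators for every study design the framework is validated
on: null Z-score panels, power scenarios for the joint tests, individual-level
GWAS (for comparison with MANOVA), LD-structured panels for imputation,
mixture panels for clustering, and sample-size-heterogeneity panels.

All generators are deterministic given their seed.  Z-scores are simulated
directly on the summary-statistic scale: a null SNP's K-vector is
``N(0, Sigma_r)`` where the residual covariance comes from sample overlap
(``sigma_z = rho * n_s / sqrt(n1 n2)`` per trait pair), and a causal SNP adds
a genetic component ``Z = Z_g + Z_res``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mtgwas.sumstats import (ConfigurationError, LDPanel, RegionSet,
                             SumstatsPanel, SumstatsTable)

_SCENARIOS = ("random_eff", "corG", "wG", "highH", "hetH", "null")


def random_correlation(K: int, seed=None) -> np.ndarray:
    """Random correlation matrix with eigenvalues drawn from a flat Dirichlet
    (scaled to sum to K) and a random orthogonal rotation."""
    if K < 2:
        raise ConfigurationError("K must be >= 2")
    rng = np.random.default_rng(seed)
    ev = rng.dirichlet(np.ones(K)) * K
    ev = np.clip(ev, 1e-6, None)
    ev = ev / ev.sum() * K
    mat = stats.random_correlation.rvs(ev, random_state=rng, tol=1e-8)
    np.fill_diagonal(mat, 1.0)
    return 0.5 * (mat + mat.T)


def overlap_sigma_r(rho: np.ndarray, overlap_fraction: float = 1.0,
                    n: np.ndarray | None = None) -> np.ndarray:
    """Residual Z covariance implied by a phenotypic correlation matrix and
    a common overlap fraction: off-diagonals rho_jk * ns / sqrt(nj nk) with
    ns = overlap_fraction * min(nj, nk); unit diagonal."""
    K = rho.shape[0]
    n = np.full(K, 1.0) if n is None else np.asarray(n, dtype=float)
    s = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            ns = overlap_fraction * min(n[i], n[j])
            s[i, j] = s[j, i] = rho[i, j] * ns / np.sqrt(n[i] * n[j])
    return s


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    ev, P = np.linalg.eigh(0.5 * (mat + mat.T))
    s = (P * np.clip(ev, 1e-8, None)) @ P.T
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    np.fill_diagonal(s, 1.0)
    return 0.5 * (s + s.T)


def simulate_null_panel(sigma_r: np.ndarray, n_snps: int, seed=None) -> np.ndarray:
    """I.i.d. null Z-score rows ~ N(0, Sigma_r)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma_r + 1e-12 * np.eye(len(sigma_r)))
    return rng.standard_normal((n_snps, len(sigma_r))) @ L.T


@dataclass
class ScenarioSpec:
    """Parameters of a power-simulation scenario.

    ``scenario`` picks the genetic-effect distribution: ``random_eff``
    (per-trait Uniform(−6, 6)), ``corG`` (multivariate normal with a random
    genetic correlation), ``wG`` (effects along one direction plus isotropic
    noise), ``highH`` (independent traits, all with strong effects),
    ``hetH`` (only the first trait has strong effects) or ``null``.
    ``residual_mode`` is ``random`` (residual correlation drawn independently
    of the genetic one) or ``aligned`` (0.4 * genetic + 0.6 * random, then
    projected to the nearest correlation matrix).
    """

    scenario: str = "random_eff"
    K: int = 10
    n_snps: int = 5000
    overlap_fraction: float = 0.5
    residual_mode: str = "random"
    effect_scale: float = 4.0       # SD of strong effects (highH/hetH/wG/corG)
    uniform_bound: float = 6.0
    wg_noise_sd: float = 1.0
    seed: int | None = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.overlap_fraction <= 1:
            raise ConfigurationError("overlap fraction must be in [0, 1]")
        if self.K < 2:
            raise ConfigurationError("K must be >= 2")


@dataclass
class PowerPanel:
    Z: np.ndarray
    causal: np.ndarray
    sigma_r: np.ndarray
    sigma_g: np.ndarray
    spec: ScenarioSpec = field(repr=False)


def simulate_power_panel(spec: ScenarioSpec) -> PowerPanel:
    """Z = Z_g + Z_res for each SNP under the chosen scenario.

    Returns the panel plus the residual covariance actually used (for
    testing) and the generating genetic covariance (for the gene_pc1
    weighting)."""
    rng = np.random.default_rng(spec.seed)
    K, n = spec.K, spec.n_snps
    s2 = spec.effect_scale ** 2

    if spec.scenario == "random_eff":
        Zg = rng.uniform(-spec.uniform_bound, spec.uniform_bound, size=(n, K))
        sigma_g = (spec.uniform_bound ** 2 / 3.0) * np.eye(K)
    elif spec.scenario == "corG":
        rho_g = random_correlation(K, rng)
        sigma_g = s2 * rho_g
        Zg = simulate_null_panel(sigma_g, n, rng)
    elif spec.scenario == "wG":
        rho_g = random_correlation(K, rng)
        w = np.linalg.eigh(rho_g)[1][:, -1]
        amp = rng.normal(0.0, spec.effect_scale, size=n)
        Zg = amp[:, None] * w[None, :] + rng.normal(
            0.0, spec.wg_noise_sd, size=(n, K))
        sigma_g = s2 * np.outer(w, w) + spec.wg_noise_sd ** 2 * np.eye(K)
    elif spec.scenario == "highH":
        Zg = rng.normal(0.0, spec.effect_scale, size=(n, K))
        sigma_g = s2 * np.eye(K)
    elif spec.scenario == "hetH":
        Zg = np.zeros((n, K))
        Zg[:, 0] = rng.normal(0.0, spec.effect_scale, size=n)
        sigma_g = np.diag([s2] + [1e-4] * (K - 1))
    else:  # null
        Zg = np.zeros((n, K))
        sigma_g = np.zeros((K, K))

    E = random_correlation(K, rng)
    if spec.residual_mode == "aligned":
        d = np.sqrt(np.diag(sigma_g))
        rho_g_corr = sigma_g / np.outer(np.maximum(d, 1e-6), np.maximum(d, 1e-6))
        np.fill_diagonal(rho_g_corr, 1.0)
        rho_r = _nearest_correlation(0.4 * rho_g_corr + 0.6 * E)
    elif spec.residual_mode == "random":
        rho_r = E
    else:
        raise ConfigurationError(f"unknown residual mode {spec.residual_mode!r}")
    sigma_r = overlap_sigma_r(rho_r, spec.overlap_fraction)
    Zres = simulate_null_panel(sigma_r, n, rng)
    causal = np.full(n, spec.scenario != "null")
    return PowerPanel(Zg + Zres, causal, sigma_r, sigma_g, spec)


# ---------------------------------------------------------------------------
# Individual-level simulation (MANOVA comparisons)


@dataclass
class IndividualLevelData:
    G: np.ndarray              # standardized genotypes, n_ind x n_snps
    Y: np.ndarray              # standardized phenotypes, n_ind x K
    causal: np.ndarray
    sigma_e: np.ndarray


def simulate_individual_level(n_ind: int = 5000, n_snps: int = 2000,
                              K: int = 5, n_causal: int = 200,
                              effect_sd: float = 0.05,
                              freq_range: tuple[float, float] = (0.01, 0.99),
                              nonnormal: bool = False,
                              seed=None) -> IndividualLevelData:
    """Genotypes binomial(2, f) with f ~ Uniform(freq_range), standardized;
    phenotypes are linear in ``n_causal`` random SNPs plus correlated normal
    noise, then optionally quantile-transformed (thirds of the traits mapped
    to uniform / Laplace / exponential margins) and re-standardized."""
    if n_ind > 10_000 or n_snps > 10_000:
        raise ConfigurationError("individual-level generator is desk-scale only")
    rng = np.random.default_rng(seed)
    f = rng.uniform(*freq_range, size=n_snps)
    G = rng.binomial(2, f, size=(n_ind, n_snps)).astype(float)
    G = (G - G.mean(axis=0)) / np.maximum(G.std(axis=0), 1e-12)
    sigma_e = random_correlation(K, rng)
    E = simulate_null_panel(sigma_e, n_ind, rng)
    B = np.zeros((n_snps, K))
    causal = np.zeros(n_snps, dtype=bool)
    if n_causal > 0:
        idx = rng.choice(n_snps, size=min(n_causal, n_snps), replace=False)
        causal[idx] = True
        B[idx] = rng.normal(0.0, effect_sd, size=(idx.size, K))
    Y = G @ B + E
    if nonnormal:
        Y = _nonnormal_transform(Y)
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    return IndividualLevelData(G, Y, causal, sigma_e)


def _nonnormal_transform(Y: np.ndarray) -> np.ndarray:
    """Map thirds of the traits to uniform / Laplace / exponential margins
    through the probability integral transform of their normal scores."""
    Y = Y.copy()
    K = Y.shape[1]
    u = stats.norm.cdf((Y - Y.mean(axis=0)) / Y.std(axis=0))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    third = max(K // 3, 1)
    for k in range(K):
        if k < third:
            Y[:, k] = u[:, k]
        elif k < 2 * third:
            Y[:, k] = stats.laplace.ppf(u[:, k])
        else:
            Y[:, k] = stats.expon.ppf(u[:, k])
    return Y


def univariate_z_scan(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-SNP per-trait univariate regression Z-scores (t on the standardized
    slope, mapped through the exact monotone t->z relation)."""
    n = G.shape[0]
    r = G.T @ Y / n
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return np.sign(t) * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2)


def manova_scan(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-SNP one-predictor MANOVA p-values via Wilks' lambda.

    With a single predictor, Wilks' lambda equals 1 - rho^2 where rho is the
    canonical correlation between the genotype and the phenotype block, and
    the F transform is exact: F = (n-K-1)/K * rho^2/(1-rho^2)."""
    n, K = Y.shape
    Ys = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    Gs = (G - G.mean(axis=0)) / np.maximum(G.std(axis=0), 1e-12)
    Ry = np.corrcoef(Ys, rowvar=False)
    r = Gs.T @ Ys / n                       # n_snps x K correlations
    rho2 = np.einsum("ij,ij->i", r, np.linalg.solve(Ry, r.T).T)
    rho2 = np.clip(rho2, 0.0, 1.0 - 1e-12)
    F = (n - K - 1) / K * rho2 / (1 - rho2)
    return stats.f.sf(F, K, n - K - 1)


# ---------------------------------------------------------------------------
# LD-structured panels (imputation, clumping, pipeline fixtures)


def simulate_ld_panel(n_regions: int = 20, snps_per_region: int = 25,
                      ar_rho: float = 0.8, region_size: int = 100_000,
                      seed=None) -> LDPanel:
    """LD reference with AR(1) correlation within blocks: r(i, j) = ar_rho^|i-j|.

    Regions tile a single synthetic chromosome; SNP alleles are drawn from
    strand-unambiguous pairs so the panel is valid as a harmonization
    reference."""
    rng = np.random.default_rng(seed)
    idx = np.arange(snps_per_region)
    mat = ar_rho ** np.abs(idx[:, None] - idx[None, :])
    regions = RegionSet(pd.DataFrame({
        "chrom": "1",
        "start": np.arange(n_regions) * region_size,
        "end": (np.arange(n_regions) + 1) * region_size}))
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
             ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
    ids, rows = [], []
    for r in range(n_regions):
        ids.append([f"rs{r}_{i}" for i in idx])
        for i in idx:
            c, o = pairs[rng.integers(len(pairs))]
            rows.append((f"rs{r}_{i}", "1", r * region_size + 1 + i * 100, c, o))
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                       "coded_allele", "other_allele"])
    return LDPanel(regions, ids, [mat.copy() for _ in range(n_regions)], snps)


def simulate_panel_with_ld(ld: LDPanel, sigma_r: np.ndarray,
                           effects: np.ndarray | None = None,
                           n: float = 50_000.0, missing_rate: float = 0.0,
                           seed=None) -> SumstatsPanel:
    """Z-scores with covariance LD (across SNPs within a region) x Sigma_r
    (across traits), plus optional mean shifts ``LD @ effects`` per region.

    ``effects`` is an (n_snps, K) matrix of direct per-SNP non-centralities;
    LD propagates a causal SNP's signal to its neighbours, as in a real GWAS.
    """
    rng = np.random.default_rng(seed)
    K = sigma_r.shape[0]
    Ls = np.linalg.cholesky(sigma_r + 1e-12 * np.eye(K))
    blocks = []
    offset = 0
    for ids, mat in zip(ld.region_snps, ld.matrices):
        m = len(ids)
        Ll = np.linalg.cholesky(mat + 1e-10 * np.eye(m))
        Z = Ll @ rng.standard_normal((m, K)) @ Ls.T
        if effects is not None:
            Z = Z + mat @ effects[offset:offset + m]
        blocks.append(Z)
        offset += m
    Z = np.vstack(blocks)
    if missing_rate > 0:
        drop = rng.random(Z.shape) < missing_rate
        Z = np.where(drop, np.nan, Z)
    N = np.full_like(Z, float(n))
    N[np.isnan(Z)] = np.nan
    traits = [f"trait_{k}" for k in range(K)]
    return SumstatsPanel(ld.snps.copy(), traits, Z, N)


def simulate_cluster_panel(pi: np.ndarray, mu: np.ndarray,
                           sigmas: np.ndarray, n_snps: int,
                           missing_rate: float = 0.0,
                           seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Mixture panel: labels ~ Multinomial(pi), rows ~ N(mu_label,
    Sigma_label), missingness completely at random."""
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ConfigurationError("pi must sum to 1")
    if not 0 <= missing_rate <= 0.6:
        raise ConfigurationError("missing_rate must be in [0, 0.6]")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(pi), size=n_snps, p=pi)
    K = mu.shape[1]
    Z = np.empty((n_snps, K))
    for j in range(len(pi)):
        sel = labels == j
        L = np.linalg.cholesky(np.asarray(sigmas[j]) + 1e-12 * np.eye(K))
        Z[sel] = mu[j] + rng.standard_normal((sel.sum(), K)) @ L.T
    if missing_rate > 0:
        drop = rng.random(Z.shape) < missing_rate
        # keep at least one observed coordinate per row
        all_gone = drop.all(axis=1)
        drop[all_gone, rng.integers(0, K, size=all_gone.sum())] = False
        Z = np.where(drop, np.nan, Z)
    return Z, labels


# ---------------------------------------------------------------------------
# Sample-size heterogeneity


def simulate_hetn_panel(rho: np.ndarray, n_snps: int, n_full: float = 100_000.0,
                        reduced_ratio: float = 0.3, reduced_prob: float = 0.3,
                        seed=None) -> tuple[SumstatsPanel, np.ndarray]:
    """Panel where a random subset of (SNP, trait) entries comes from a nested
    subsample of ``reduced_ratio * n_full`` individuals.

    Each SNP's true residual covariance then depends on its per-trait sample
    sizes (overlap = the smaller nested sample), so testing every SNP against
    the single full-overlap covariance is a misspecification — until the
    small-n entries are filtered out.  Returns the panel and the full-overlap
    Sigma_r."""
    rng = np.random.default_rng(seed)
    K = rho.shape[0]
    reduced = rng.random((n_snps, K)) < reduced_prob
    n_mat = np.where(reduced, reduced_ratio * n_full, n_full)
    Z = np.empty((n_snps, K))
    pats, inv = np.unique(reduced, axis=0, return_inverse=True)
    for pi in range(len(pats)):
        rows = np.where(inv == pi)[0]
        n_vec = np.where(pats[pi], reduced_ratio * n_full, n_full)
        s = np.eye(K)
        for i in range(K):
            for j in range(i + 1, K):
                ns = min(n_vec[i], n_vec[j])
                s[i, j] = s[j, i] = rho[i, j] * ns / np.sqrt(n_vec[i] * n_vec[j])
        Z[rows] = simulate_null_panel(s, rows.size, rng)
    snps = pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n_snps)], "chrom": "1",
        "pos": np.arange(1, n_snps + 1), "coded_allele": "A",
        "other_allele": "G"})
    traits = [f"trait_{k}" for k in range(K)]
    panel = SumstatsPanel(snps, traits, Z, n_mat.astype(float))
    sigma_full = np.eye(K) + rho * (1 - np.eye(K))
    return panel, sigma_full


# ---------------------------------------------------------------------------
# Per-trait GWAS tables for the preprocessing checks


def simulate_linear_gwas(n_ind: int = 20_000, n_snps: int = 500,
                         seed=None) -> SumstatsTable:
    """Null linear-model GWAS of a standardized outcome: per-SNP beta, se,
    p and coded-allele frequency, with the sample-size column left missing
    (the target of the inference proxy)."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.05, 0.95, size=n_snps)
    y = rng.standard_normal(n_ind)
    y = (y - y.mean()) / y.std()
    beta = np.empty(n_snps)
    se = np.empty(n_snps)
    for i in range(n_snps):
        g = rng.binomial(2, f[i], size=n_ind).astype(float)
        gc = g - g.mean()
        vg = (gc ** 2).mean()
        b = (gc @ y) / (n_ind * vg)
        resid = y - b * gc
        s2 = (resid ** 2).sum() / (n_ind - 2)
        beta[i] = b
        se[i] = np.sqrt(s2 / (n_ind * vg))
    p = 2 * stats.norm.sf(np.abs(beta / se))
    df = pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n_snps)], "chrom": "1",
        "pos": np.arange(1, n_snps + 1), "coded_allele": "A",
        "other_allele": "G", "beta": beta, "se": se, "pvalue": p, "freq": f})
    return SumstatsTable(df, trait="linear_sim")


def simulate_logistic_gwas(n_ind: int = 20_000, case_fraction: float = 0.3,
                           n_snps: int = 200, seed=None) -> SumstatsTable:
    """Null case/control GWAS fitted by per-SNP logistic regression (Newton
    iterations on the two-parameter model); se comes from the observed
    information, so 1/(se^2 * 2f(1-f)) targets N * p * (1 - p)."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.9, size=n_snps)
    y = (rng.random(n_ind) < case_fraction).astype(float)
    beta = np.empty(n_snps)
    se = np.empty(n_snps)
    for i in range(n_snps):
        g = rng.binomial(2, f[i], size=n_ind).astype(float)
        X = np.column_stack([np.ones(n_ind), g])
        coef = np.zeros(2)
        for _ in range(25):
            eta = X @ coef
            mu = 1.0 / (1.0 + np.exp(-eta))
            W = mu * (1 - mu)
            H = (X * W[:, None]).T @ X
            gvec = X.T @ (y - mu)
            step = np.linalg.solve(H, gvec)
            coef += step
            if np.abs(step).max() < 1e-10:
                break
        cov = np.linalg.inv(H)
        beta[i] = coef[1]
        se[i] = np.sqrt(cov[1, 1])
    p = 2 * stats.norm.sf(np.abs(beta / se))
    df = pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n_snps)], "chrom": "1",
        "pos": np.arange(1, n_snps + 1), "coded_allele": "A",
        "other_allele": "G", "beta": beta, "se": se, "pvalue": p, "freq": f})
    return SumstatsTable(df, trait="logit_sim")


def simulate_ld_scores(ld: LDPanel) -> np.ndarray:
    """Per-SNP LD scores (sum of squared within-region correlations)."""
    return np.concatenate([(m ** 2).sum(axis=1) for m in ld.matrices])


def simulate_ldsc_panel(sigma_r: np.ndarray, sigma_g: np.ndarray,
                        n: float, m_snps: int, seed=None
                        ) -> tuple[SumstatsPanel, np.ndarray]:
    """Polygenic panel on the LD-score regression model: per SNP j with LD
    score ell_j, z_j ~ N(0, Sigma_r + (ell_j * n / M) * Sigma_g).

    LD scores are drawn from a shifted exponential (mean ~ 40), mimicking the
    long-tailed genome-wide distribution.  Returns (panel, ld_scores)."""
    rng = np.random.default_rng(seed)
    K = sigma_r.shape[0]
    ell = 1.0 + rng.exponential(39.0, size=m_snps)
    Z = np.empty((m_snps, K))
    # bin LD scores so each bin shares one cholesky factor
    bins = np.quantile(ell, np.linspace(0, 1, 51))
    which = np.clip(np.searchsorted(bins, ell) - 1, 0, 49)
    for b in range(50):
        rows = np.where(which == b)[0]
        if rows.size == 0:
            continue
        ell_b = ell[rows].mean()
        cov = sigma_r + (ell_b * n / m_snps) * sigma_g
        Z[rows] = simulate_null_panel(cov, rows.size, rng)
    snps = pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(m_snps)], "chrom": "1",
        "pos": np.arange(1, m_snps + 1), "coded_allele": "A",
        "other_allele": "G"})
    traits = [f"trait_{k}" for k in range(K)]
    panel = SumstatsPanel(snps, traits, Z, np.full((m_snps, K), float(n)))
    return panel, ell
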