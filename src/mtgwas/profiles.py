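"""Per-cluster genetic covariance/correlation with sample-overlap bias
correction, allele alignment along a cluster's first principal component,
variance-explained decomposition, and sign tests against external traits.

Standardized effects are beta_hat = z / sqrt(N).  For two traits whose
studies share n_s samples with phenotypic covariance rho_Y, the product of
estimated effects is biased upward by ``n_s * rho_Y / (n1 * n2)`` per SNP;
subtracting that term per SNP gives an unbiased per-SNP contribution to the
cluster genetic covariance and a t-test for its mean being zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mtgwas.sumstats import ConfigurationError

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few SNPs to run the requested per-cluster analysis."""


@dataclass
class ClusterCorrelation:
    """Corrected genetic covariance and correlation for one trait pair."""

    covariance: float
    correlation: float            # NaN when a corrected variance is <= 0
    t_statistic: float
    pvalue: float
    m_snps: int


def cluster_genetic_covariance(beta1: np.ndarray, beta2: np.ndarray,
                               n1: float, n2: float, ns: float = 0.0,
                               rho_y: float = 0.0) -> ClusterCorrelation:
    """Overlap-corrected genetic covariance between two traits over a
    cluster's independent SNPs.

    Per SNP j the contribution is ``X_j = b1_j b2_j - ns rho_y / (n1 n2)``;
    the estimate is mean(X_j) and significance a two-sided one-sample t-test
    of mean zero.  The correlation divides by corrected per-trait variances
    ``mean(b^2 - 1/n)`` (the 1/n term is the sampling variance of a
    standardized effect); it is reported NaN if either corrected variance is
    non-positive.
    """
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    if b1.shape != b2.shape:
        raise ConfigurationError("effect vectors must have equal length")
    M = b1.size
    if M < 5:
        raise InsufficientDataError(f"only {M} SNPs in cluster; need >= 5")
    bias = ns * rho_y / (n1 * n2)
    X = b1 * b2 - bias
    est = float(X.mean())
    t, p = stats.ttest_1samp(X, 0.0)
    v1 = float(np.mean(b1 ** 2 - 1.0 / n1))
    v2 = float(np.mean(b2 ** 2 - 1.0 / n2))
    corr = est / np.sqrt(v1 * v2) if (v1 > 0 and v2 > 0) else np.nan
    return ClusterCorrelation(est, corr, float(t), float(p), M)


def cluster_correlation_table(B: np.ndarray, N: np.ndarray, labels: np.ndarray,
                              Ns: np.ndarray | None = None,
                              rho_y: np.ndarray | None = None,
                              traits: list[str] | None = None) -> pd.DataFrame:
    """All trait pairs x clusters, with a Bonferroni flag across the table."""
    K = B.shape[1]
    traits = traits or [f"t{i}" for i in range(K)]
    Ns = Ns if Ns is not None else np.zeros((K, K))
    rho_y = rho_y if rho_y is not None else np.zeros((K, K))
    rows = []
    for c in np.unique(labels):
        sel = labels == c
        for i in range(K):
            for j in range(i + 1, K):
                try:
                    r = cluster_genetic_covariance(
                        B[sel, i], B[sel, j], N[i], N[j], Ns[i, j], rho_y[i, j])
                except InsufficientDataError:
                    continue
                rows.append({"cluster": c, "trait1": traits[i],
                             "trait2": traits[j], "covariance": r.covariance,
                             "correlation": r.correlation, "t": r.t_statistic,
                             "pvalue": r.pvalue, "m_snps": r.m_snps})
    out = pd.DataFrame(rows)
    if len(out):
        out["bonferroni_significant"] = out["pvalue"] < 0.05 / len(out)
    return out


def cluster_pc1(B: np.ndarray, n_shuffles: int = 20,
                seed: int | None = 0) -> tuple[np.ndarray, float]:
    """First principal component of a cluster's SNP x trait effect matrix,
    averaged over random re-codings of the coded allele.

    The coded allele of each SNP is arbitrary, so each shuffle flips random
    SNP rows' signs before the (column-centered) PCA; PC1 of each replicate
    is sign-aligned to the first and the loadings averaged and renormalized.
    Also returns the mean fraction of variance explained by PC1.
    """
    B = np.asarray(B, dtype=float)
    n, K = B.shape
    if n < K:
        raise InsufficientDataError(f"cluster has {n} SNPs < {K} traits")
    if np.allclose(B.std(axis=0), 0):
        raise ConfigurationError("degenerate (zero-variance) effect matrix")
    rng = np.random.default_rng(seed)
    ref = None
    loadings = np.zeros(K)
    var_frac = 0.0
    for s in range(n_shuffles):
        signs = rng.choice([-1.0, 1.0], size=n)
        X = B * signs[:, None]
        X = X - X.mean(axis=0)
        _, svals, Vt = np.linalg.svd(X, full_matrices=False)
        v = Vt[0]
        if ref is None:
            v = v * np.sign(v[np.argmax(np.abs(v))] or 1.0)
            ref = v
        elif v @ ref < 0:
            v = -v
        loadings += v
        var_frac += svals[0] ** 2 / (svals ** 2).sum()
    loadings /= np.linalg.norm(loadings)
    return loadings, var_frac / n_shuffles


def align_alleles_to_pc1(profile: np.ndarray, pc1: np.ndarray) -> np.ndarray:
    """Flip a SNP's multitrait profile so it points along the cluster's PC1.

    The sign is flipped iff the dot product with the loading vector is
    negative; an exactly orthogonal profile is kept as-is and logged."""
    profile = np.asarray(profile, dtype=float)
    d = float(np.nansum(profile * pc1))
    if d == 0.0:
        logger.info("profile orthogonal to PC1: orientation left unchanged")
        return profile
    return profile if d > 0 else -profile


def disease_sign_test(z: np.ndarray) -> tuple[float, str]:
    """Exact two-sided sign test on PC1-aligned Z-scores of an external trait.

    Zero Z-scores are excluded; at least five nonzero signs are required.
    Returns (p-value, majority direction in {"positive", "negative", "even"}).
    """
    z = np.asarray(z, dtype=float)
    z = z[~np.isnan(z) & (z != 0)]
    if z.size < 5:
        raise InsufficientDataError(f"only {z.size} nonzero signs; need >= 5")
    n_pos = int((z > 0).sum())
    res = stats.binomtest(n_pos, z.size, 0.5, alternative="two-sided")
    direction = ("positive" if n_pos * 2 > z.size
                 else "negative" if n_pos * 2 < z.size else "even")
    return float(res.pvalue), direction


def variance_explained_matrix(Z: np.ndarray, N: np.ndarray,
                              labels: np.ndarray,
                              traits: list[str] | None = None,
                              display_floor: float = 0.001) -> pd.DataFrame:
    """Cluster x trait shares of explained phenotypic variance.

    A SNP's contribution to a trait is ``z^2 / n`` (the squared standardized
    effect); shares are normalized per trait over all selected SNPs so each
    column sums to one.  Shares below ``display_floor`` get a ``below_floor``
    flag (typically left out of alluvial displays).
    """
    Z = np.asarray(Z, dtype=float)
    N = np.asarray(N, dtype=float)
    contrib = np.nan_to_num(Z ** 2 / N, nan=0.0)
    totals = contrib.sum(axis=0)
    K = Z.shape[1]
    traits = traits or [f"t{i}" for i in range(K)]
    rows = []
    for c in np.unique(labels):
        share = contrib[labels == c].sum(axis=0) / np.where(totals > 0, totals, np.nan)
        for t in range(K):
            rows.append({"cluster": c, "trait": traits[t],
                         "share": float(share[t]),
                         "below_floor": bool(share[t] < display_floor)})
    return pd.DataFrame(rows)
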