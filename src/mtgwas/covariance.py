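"""Estimation of the null Z-score covariance Sigma_r (and the genetic
covariance Sigma_g), plus the pseudo-inverse machinery used by the joint
tests.

Under the complete null, cov(z1, z2) between two studies equals
``rho * ns / sqrt(n1 * n2)`` where ``ns`` is the number of overlapping samples
and ``rho`` the phenotypic covariance among them.  When the overlap
parameters are unknown, Sigma_r is estimated from genome-wide Z-scores
either directly (naive / pruned / trimmed moment estimators) or by
LD-score regression, whose intercept isolates the overlap term from the
polygenic slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtgwas.sumstats import ConfigurationError, SumstatsPanel


class EstimationError(RuntimeError):
    """Raised when a covariance cannot be estimated from the data given."""


class SingularityError(np.linalg.LinAlgError):
    """Raised when no usable inverse subspace remains."""


@dataclass
class NullCovariance:
    """K x K residual covariance of Z-scores, with optional genetic covariance.

    ``rank`` is the number of eigenvalues of ``sigma_r`` above 1e-9 times the
    largest; ``method`` records provenance.  ``se_r`` holds jackknife standard
    errors where the estimator provides them.
    """

    sigma_r: np.ndarray
    sigma_g: np.ndarray | None = None
    method: str = "external"
    se_r: np.ndarray | None = None
    traits: list[str] | None = None
    rank: int = field(init=False)

    def __post_init__(self):
        s = np.asarray(self.sigma_r, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ConfigurationError("sigma_r must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ConfigurationError("sigma_r must be symmetric")
        if (np.diag(s) <= 0).any():
            raise ConfigurationError("sigma_r diagonal must be positive")
        self.sigma_r = 0.5 * (s + s.T)
        ev = np.linalg.eigvalsh(self.sigma_r)
        self.rank = int((ev > 1e-9 * ev.max()).sum())

    @property
    def k(self) -> int:
        return self.sigma_r.shape[0]

    def save(self, path: str) -> None:
        names = self.traits or [f"t{i}" for i in range(self.k)]
        pd.DataFrame(self.sigma_r, index=names, columns=names).to_csv(
            path, sep="\t", float_format="%.17g")

    @classmethod
    def load(cls, path: str, method: str = "external") -> "NullCovariance":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.values, method=method, traits=list(df.columns))


def theoretical_sigma_r(n1: float, n2: float, ns: float, rho: float) -> float:
    """Expected null Z-score covariance: rho * ns / sqrt(n1 * n2)."""
    if not (n1 > 0 and n2 > 0):
        raise ConfigurationError("sample sizes must be positive")
    if ns < 0 or ns > min(n1, n2):
        raise ConfigurationError("overlap ns must satisfy 0 <= ns <= min(n1, n2)")
    if not -1 <= rho <= 1:
        raise ConfigurationError("rho must lie in [-1, 1]")
    return rho * ns / np.sqrt(n1 * n2)


def sigma_r_from_overlap(N: np.ndarray, Ns: np.ndarray,
                         rho: np.ndarray) -> np.ndarray:
    """Assemble Sigma_r from per-trait sizes, pairwise overlaps and phenotypic
    correlations; unit diagonal.  Clips tiny negative eigenvalues to keep the
    result positive semi-definite when the overlap pattern is inconsistent."""
    N = np.asarray(N, dtype=float)
    K = len(N)
    s = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            s[i, j] = s[j, i] = theoretical_sigma_r(N[i], N[j], Ns[i, j], rho[i, j])
    ev, P = np.linalg.eigh(s)
    if ev.min() < 0:
        s = (P * np.clip(ev, 1e-10, None)) @ P.T
        d = np.sqrt(np.diag(s))
        s = s / np.outer(d, d)
    return 0.5 * (s + s.T)


def empirical_sigma_r(panel: SumstatsPanel, mode: str = "naive",
                      trim_p: float | None = 5e-8,
                      subsample: int | None = 20_000,
                      min_pairs: int = 1000,
                      seed: int | None = 0) -> NullCovariance:
    """Moment estimator of Sigma_r from genome-wide Z-scores.

    Modes: ``naive`` uses every SNP; ``pruned`` uses a random subset of
    ``subsample`` SNPs (a stand-in for LD pruning when SNPs are exchangeable);
    ``trimmed`` removes SNPs significant in any trait at ``trim_p`` first,
    which reduces the contamination of the off-diagonal by causal SNPs.  Pairwise-complete covariance is used because panels are missing by
    design.
    """
    Z = panel.Z
    if mode == "trimmed":
        from scipy import stats
        p = 2 * stats.norm.sf(np.abs(Z))
        hit = np.nanmin(np.where(np.isnan(p), np.inf, p), axis=1) < trim_p
        Z = Z[~hit]
    elif mode == "pruned":
        rng = np.random.default_rng(seed)
        if subsample is not None and subsample < len(Z):
            Z = Z[rng.choice(len(Z), size=subsample, replace=False)]
    elif mode != "naive":
        raise ConfigurationError(f"unknown mode {mode!r}")
    df = pd.DataFrame(Z)
    complete = (~np.isnan(Z)).astype(int)
    pair_counts = complete.T @ complete
    if pair_counts.min() < min_pairs:
        raise EstimationError(
            f"fewest pairwise-complete observations {pair_counts.min()} "
            f"< required {min_pairs}")
    cov = df.cov(min_periods=min_pairs).values
    return NullCovariance(cov, method=mode, traits=list(panel.traits))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
    return float(beta[0]), float(beta[1])


def ldsc_sigma(panel: SumstatsPanel, ld_scores: np.ndarray,
               m_snps: int | None = None, n_blocks: int = 200) -> NullCovariance:
    """LD-score regression estimate of Sigma_r (intercepts) and Sigma_g (slopes).

    For each trait pair (j, k) the products ``z_j * z_k`` are regressed on the
    per-SNP LD score with weights 1/max(ell, 1): the intercept estimates the
    overlap-induced covariance (Sigma_r)_jk and ``slope * M / sqrt(nj nk)``
    the genetic covariance; the per-trait diagonal comes from regressing
    ``z^2`` on the LD score.  Intercept standard errors are computed by a
    block jackknife over ``n_blocks`` contiguous SNP blocks.
    """
    ell = np.asarray(ld_scores, dtype=float)
    if (ell <= 0).any():
        raise ConfigurationError("LD scores must be positive")
    if np.ptp(ell) == 0:
        raise EstimationError("constant LD scores: slope is not identifiable")
    Z, N = panel.Z, panel.N
    K = panel.n_traits
    M = m_snps if m_snps is not None else panel.n_snps
    w = 1.0 / np.maximum(ell, 1.0)
    sr = np.eye(K)
    sg = np.zeros((K, K))
    se = np.zeros((K, K))
    for j in range(K):
        for k in range(j, K):
            obs = ~np.isnan(Z[:, j]) & ~np.isnan(Z[:, k])
            if obs.sum() < max(50, 2 * n_blocks):
                raise EstimationError("too few pairwise-complete SNPs for LDSC")
            y = Z[obs, j] * Z[obs, k]
            x, wt = ell[obs], w[obs]
            icpt, slope = _wls(x, y, wt)
            n_eff = np.sqrt(np.nanmean(N[obs, j]) * np.nanmean(N[obs, k]))
            sr[j, k] = sr[k, j] = icpt
            sg[j, k] = sg[k, j] = slope * M / n_eff
            # delete-one-block jackknife on the intercept
            blocks = np.array_split(np.arange(obs.sum()), n_blocks)
            pseudo = []
            for b in blocks:
                keep = np.ones(obs.sum(), dtype=bool)
                keep[b] = False
                pseudo.append(_wls(x[keep], y[keep], wt[keep])[0])
            pseudo = np.asarray(pseudo)
            nb = len(pseudo)
            se[j, k] = se[k, j] = np.sqrt((nb - 1) / nb * ((pseudo - pseudo.mean()) ** 2).sum())
    if (np.diag(sr) <= 0).any():
        raise EstimationError("negative fitted diagonal of Sigma_r; "
                              "check input Z-scores and LD scores")
    return NullCovariance(sr, sigma_g=0.5 * (sg + sg.T), method="ldsc",
                          se_r=se, traits=list(panel.traits))


@dataclass
class PseudoInverse:
    """Inverse operator for a (possibly singular) covariance matrix."""

    matrix: np.ndarray
    df: int
    strategy: str
    epsilon: float


def pseudo_inverse(cov: NullCovariance | np.ndarray, strategy: str = "truncate",
                   epsilon: float = 1e-6) -> PseudoInverse:
    """Eigen-based inverse of Sigma_r with an explicit singularity policy.

    ``truncate`` keeps the eigenvectors with eigenvalue > epsilon and inverts
    on that subspace (the chi-square degrees of freedom drop to the retained
    rank K'); ``floor`` raises small eigenvalues to epsilon; ``ridge`` inverts
    Sigma_r + epsilon I.  ``floor`` and ``ridge`` keep df = K.
    """
    s = cov.sigma_r if isinstance(cov, NullCovariance) else np.asarray(cov, float)
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    K = s.shape[0]
    ev, P = np.linalg.eigh(0.5 * (s + s.T))
    if strategy == "truncate":
        keep = ev > epsilon
        if not keep.any():
            raise SingularityError("all eigenvalues below epsilon under truncate")
        inv = (P[:, keep] / ev[keep]) @ P[:, keep].T
        return PseudoInverse(inv, int(keep.sum()), strategy, epsilon)
    if strategy == "floor":
        ev2 = np.maximum(ev, epsilon)
        return PseudoInverse((P / ev2) @ P.T, K, strategy, epsilon)
    if strategy == "ridge":
        return PseudoInverse(np.linalg.inv(s + epsilon * np.eye(K)), K,
                             strategy, epsilon)
    raise ConfigurationError(f"unknown strategy {strategy!r}")
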