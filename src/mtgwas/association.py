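"""Joint association tests on a vector of K per-trait Z-scores.

Two families are provided.  The omnibus test is the K-degree-of-freedom Wald
statistic ``T = z' Sigma_r^- z`` (pseudo-inverse when Sigma_r is singular;
degrees of freedom drop to the retained rank).  The sumZ tests project z on
a weight vector w and form the 1-df statistic ``(w'z)^2 / (w' Sigma_r w)``;
four weighting schemes are supported (equal weights, first eigenvector of
the phenotypic or of the genetic covariance, and an ICA-derived direction).
The omnibus statistic decomposes exactly into the sum of sumZ statistics
taken over the eigenvectors of Sigma_r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mtgwas.covariance import NullCovariance, PseudoInverse, pseudo_inverse
from mtgwas.sumstats import ConfigurationError, SumstatsPanel

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """A length-K weight vector for sumZ tests with provenance metadata."""

    w: np.ndarray
    scheme: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if not np.isfinite(w).all() or not np.any(w != 0):
            raise ConfigurationError("weights must be finite and not all zero")
        self.w = w


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    test: str


def _chi2_result(stat: float, df: int, test: str) -> TestResult:
    return TestResult(float(stat), int(df), float(stats.chi2.sf(stat, df)), test)


def omnibus_test(z: np.ndarray, cov: NullCovariance,
                 inverse_strategy: str = "truncate", epsilon: float = 1e-6,
                 missing: str = "error") -> TestResult:
    """Omnibus Wald test of a single SNP's Z-score vector.

    ``missing="subset"`` tests the observed sub-vector against the matching
    sub-matrix of Sigma_r (df = retained rank of the sub-matrix); the default
    expects a complete vector, imputation having happened upstream.
    """
    z = np.asarray(z, dtype=float)
    obs = ~np.isnan(z)
    if not obs.all():
        if missing != "subset":
            raise ConfigurationError(
                "z contains missing values; impute first or use missing='subset'")
        if not obs.any():
            raise ConfigurationError("entirely missing z vector")
        sub = NullCovariance(cov.sigma_r[np.ix_(obs, obs)], method=cov.method)
        return omnibus_test(z[obs], sub, inverse_strategy, epsilon)
    pinv = pseudo_inverse(cov, inverse_strategy, epsilon)
    stat = float(z @ pinv.matrix @ z)
    return _chi2_result(stat, pinv.df, "omnibus")


def omnibus_scan(Z: np.ndarray, cov: NullCovariance,
                 inverse_strategy: str = "truncate", epsilon: float = 1e-6,
                 missing: str = "subset") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized omnibus test over an (n_snps, K) Z matrix.

    Rows are grouped by missingness pattern; each pattern's sub-matrix of
    Sigma_r is inverted once.  Returns (statistic, df, pvalue) arrays; rows
    with no observed value get NaN.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    stat = np.full(n, np.nan)
    df = np.zeros(n, dtype=int)
    obs = ~np.isnan(Z)
    if missing == "error" and not obs.all():
        raise ConfigurationError("Z contains missing values")
    patterns, inverse_idx = np.unique(obs, axis=0, return_inverse=True)
    for pi, pat in enumerate(patterns):
        rows = inverse_idx == pi
        if not pat.any():
            continue
        sub = cov.sigma_r[np.ix_(pat, pat)]
        pinv = pseudo_inverse(NullCovariance(sub), inverse_strategy, epsilon)
        Zs = Z[np.ix_(rows, pat)]
        stat[rows] = np.einsum("ij,jk,ik->i", Zs, pinv.matrix, Zs)
        df[rows] = pinv.df
    pval = np.where(df > 0, stats.chi2.sf(stat, np.maximum(df, 1)), np.nan)
    return stat, df, pval


def sumz_test(z: np.ndarray, w: WeightVector | np.ndarray,
              cov: NullCovariance) -> TestResult:
    """1-df test of the weighted Z-score sum: (w'z)^2 / (w' Sigma_r w)."""
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    scheme = w.scheme if isinstance(w, WeightVector) else "custom"
    z = np.asarray(z, dtype=float)
    den = float(wv @ cov.sigma_r @ wv)
    if den <= 0:
        raise ConfigurationError("degenerate weights: w' Sigma_r w <= 0")
    stat = float(wv @ z) ** 2 / den
    return _chi2_result(stat, 1, f"sumz_{scheme}")


def sumz_scan(Z: np.ndarray, w: WeightVector | np.ndarray,
              cov: NullCovariance) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized sumZ test; missing entries are handled by restricting w and
    Sigma_r to each row's observed coordinates.  Returns (statistic, pvalue)."""
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    Z = np.asarray(Z, dtype=float)
    obs = ~np.isnan(Z)
    stat = np.full(Z.shape[0], np.nan)
    patterns, inverse_idx = np.unique(obs, axis=0, return_inverse=True)
    for pi, pat in enumerate(patterns):
        rows = inverse_idx == pi
        ws = wv[pat]
        if not pat.any() or not np.any(ws != 0):
            continue
        den = float(ws @ cov.sigma_r[np.ix_(pat, pat)] @ ws)
        if den <= 0:
            continue
        num = Z[np.ix_(rows, pat)] @ ws
        stat[rows] = num ** 2 / den
    pval = stats.chi2.sf(stat, 1)
    return stat, pval


def _principal_eigvec(mat: np.ndarray) -> tuple[np.ndarray, bool]:
    ev, P = np.linalg.eigh(mat)
    degenerate = np.isclose(ev[-1], ev[0], rtol=1e-8, atol=1e-12)
    v = P[:, -1]
    # deterministic sign: largest-magnitude loading positive
    v = v * np.sign(v[np.argmax(np.abs(v))] or 1.0)
    return v, bool(degenerate)


def make_weights(cov: NullCovariance, panel: SumstatsPanel | None = None,
                 scheme: str = "unit", seed: int = 0,
                 region_index: np.ndarray | None = None,
                 threshold: float = 1e-8) -> WeightVector:
    """Build a sumZ weight vector.

    ``unit``: all ones.  ``pheno_pc1``: first eigenvector of Sigma_r (with an
    isotropic Sigma_r the direction is undefined; the first canonical axis is
    returned with a warning).  ``gene_pc1``: first eigenvector of Sigma_g.
    ``ica``: FastICA on the complete genome-wide Z matrix; the component kept
    is the one whose sumZ test finds the most associations at ``threshold``
    that no univariate test finds (counted per region when ``region_index``
    is given, per SNP otherwise), ties broken by total significant count then
    component index.
    """
    K = cov.k
    if scheme == "unit":
        return WeightVector(np.ones(K), "unit")
    if scheme == "pheno_pc1":
        v, degenerate = _principal_eigvec(cov.sigma_r)
        if degenerate:
            logger.warning("isotropic Sigma_r: pheno_pc1 undefined, "
                           "returning the first canonical axis")
            v = np.eye(K)[0]
        return WeightVector(v, "pheno_pc1")
    if scheme == "gene_pc1":
        if cov.sigma_g is None:
            raise ConfigurationError("gene_pc1 requires Sigma_g")
        v, _ = _principal_eigvec(cov.sigma_g)
        return WeightVector(v, "gene_pc1")
    if scheme == "ica":
        return _ica_weights(cov, panel, seed, region_index, threshold)
    raise ConfigurationError(f"unknown weighting scheme {scheme!r}")


def _ica_weights(cov: NullCovariance, panel: SumstatsPanel | None, seed: int,
                 region_index: np.ndarray | None, threshold: float) -> WeightVector:
    from sklearn.decomposition import FastICA

    if panel is None:
        raise ConfigurationError("ica weights require a panel")
    missing_rate = np.isnan(panel.Z).mean()
    if missing_rate > 0.20:
        raise ConfigurationError(
            f"panel is {missing_rate:.0%} missing after imputation; "
            "ICA needs a (near-)complete Z matrix")
    complete = ~np.isnan(panel.Z).any(axis=1)
    Zc = panel.Z[complete]
    K = panel.n_traits
    ica = FastICA(n_components=K, algorithm="deflation", random_state=seed,
                  max_iter=500, whiten="unit-variance")
    ica.fit(Zc)
    p_univ = 2 * stats.norm.sf(np.abs(panel.Z))
    univ_min = np.nanmin(np.where(np.isnan(p_univ), np.inf, p_univ), axis=1)
    reg = region_index if region_index is not None else np.arange(panel.n_snps)

    def counts(w):
        _, p = sumz_scan(panel.Z, w, cov)
        sig = np.nan_to_num(p, nan=1.0) < threshold
        novel = sig & (univ_min >= threshold)
        sig_regions = len(np.unique(reg[sig]))
        novel_regions = len(np.unique(reg[novel]))
        return novel_regions, sig_regions

    best, best_key = 0, None
    for i, w in enumerate(ica.components_):
        novel_regions, sig_regions = counts(w)
        key = (novel_regions, sig_regions, -i)
        if best_key is None or key > best_key:
            best, best_key = i, key
    w = ica.components_[best]
    w = w * np.sign(w[np.argmax(np.abs(w))] or 1.0)
    return WeightVector(w, "ica", meta={"component": best, "seed": seed,
                                        "novel": best_key[0], "signif": best_key[1]})


def omnibus_eigen_identity(z: np.ndarray, cov: NullCovariance,
                           epsilon: float = 1e-6) -> np.ndarray:
    """Per-eigenvector sumZ statistics whose sum equals the omnibus statistic.

    For eigenpairs (lambda_i, v_i) of Sigma_r with lambda_i > epsilon the
    statistic ``(v_i' z)^2 / lambda_i`` is returned for each retained i.
    """
    z = np.asarray(z, dtype=float)
    ev, P = np.linalg.eigh(cov.sigma_r)
    keep = ev > epsilon
    proj = P[:, keep].T @ z
    return proj ** 2 / ev[keep]
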