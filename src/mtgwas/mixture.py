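"""Gaussian mixture clustering of multitrait association profiles with
missing values, fitted by EM.

Each SNP's Z-score profile is modelled as drawn from one of k multivariate
normal components (mean mu_j, covariance Sigma_j, mixing weights pi).  With
coordinates missing at random, the E-step evaluates each component's density
on the observed sub-vector only and computes the conditional mean and
covariance of the missing block given the observed one; the M-step updates
the parameters from these completed sufficient statistics, so no imputation
outside the model is needed.  Assignment ambiguity is scored by the entropy
of the posterior membership probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_score

from mtgwas.sumstats import ConfigurationError

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class ComponentCollapseError(RuntimeError):
    """A mixture component lost all support and re-seeding did not help."""


def _patterns(mask: np.ndarray):
    """Group rows by observation pattern: yields (pattern, row_indices)."""
    pats, inv = np.unique(mask, axis=0, return_inverse=True)
    for pi in range(len(pats)):
        yield pats[pi], np.where(inv == pi)[0]


class MissingDataGMM(DensityMixin, BaseEstimator):
    """Gaussian mixture model fitted by EM on data with missing coordinates.

    Parameters
    ----------
    n_components : number of clusters k (>= 1).
    n_init : random restarts; the best final log-likelihood is kept.
    ridge : floor applied to covariance eigenvalues to prevent collapse.
    random_state : seed for initialization and restarts.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, covariances_ : mixture parameters, components ordered
        by the first coordinate of their means so labels are stable.
    responsibilities_, entropies_ : per-row posterior membership and its
        entropy (natural log).
    loglik_trace_ : per-iteration total log-likelihood of the kept restart.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 200,
                 tol: float = 1e-6, n_init: int = 5, ridge: float = 1e-6,
                 random_state: int | None = None, weights_init=None,
                 means_init=None, covariances_init=None):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.ridge = ridge
        self.random_state = random_state
        self.weights_init = weights_init
        self.means_init = means_init
        self.covariances_init = covariances_init

    # -- internals ---------------------------------------------------------

    def _prepare(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ConfigurationError("X must be 2-dimensional")
        mask = ~np.isnan(X)
        if (~mask.any(axis=1)).any():
            raise ConfigurationError("every row needs at least one observed value")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        return X, mask

    def _floor_cov(self, S):
        S = 0.5 * (S + S.T)
        ev, P = np.linalg.eigh(S)
        if ev.min() < self.ridge:
            S = (P * np.maximum(ev, self.ridge)) @ P.T
        return S

    def _estep(self, X, mask, pi, mu, Sigma, groups=None):
        """Log responsibilities and per-row log marginal likelihood."""
        n, K = X.shape
        k = len(pi)
        logr = np.empty((n, k))
        for pat, rows in (groups if groups is not None else _patterns(mask)):
            o = np.where(pat)[0]
            Xo = X[np.ix_(rows, o)]
            for j in range(k):
                Soo = Sigma[j][np.ix_(o, o)]
                L = np.linalg.cholesky(Soo)
                diff = Xo - mu[j][o]
                sol = np.linalg.solve(L, diff.T)
                mahal = (sol ** 2).sum(axis=0)
                logdet = 2.0 * np.log(np.diag(L)).sum()
                logr[rows, j] = (np.log(pi[j]) - 0.5 *
                                 (o.size * _LOG2PI + logdet + mahal))
        lognorm = logsumexp(logr, axis=1)
        return logr - lognorm[:, None], lognorm

    def _mstep(self, X, mask, R, mu, Sigma, groups=None):
        n, K = X.shape
        k = R.shape[1]
        Nj = R.sum(axis=0)
        sum_x = np.zeros((k, K))
        sum_xx = np.zeros((k, K, K))
        for pat, rows in (groups if groups is not None else _patterns(mask)):
            o = np.where(pat)[0]
            m = np.where(~pat)[0]
            Xo = X[np.ix_(rows, o)]
            for j in range(k):
                w = R[rows, j]
                xhat = np.zeros((rows.size, K))
                xhat[:, o] = Xo
                C = np.zeros((K, K))
                if m.size:
                    Soo = Sigma[j][np.ix_(o, o)]
                    Smo = Sigma[j][np.ix_(m, o)]
                    A = np.linalg.solve(Soo, Smo.T).T
                    xhat[:, m] = mu[j][m] + (Xo - mu[j][o]) @ A.T
                    C[np.ix_(m, m)] = (Sigma[j][np.ix_(m, m)] - A @ Smo.T)
                sum_x[j] += w @ xhat
                sum_xx[j] += (xhat * w[:, None]).T @ xhat + w.sum() * C
        pi = Nj / n
        mu_new = sum_x / Nj[:, None]
        Sigma_new = np.empty((k, K, K))
        for j in range(k):
            S = sum_xx[j] / Nj[j] - np.outer(mu_new[j], mu_new[j])
            Sigma_new[j] = self._floor_cov(S)
        return pi, mu_new, Sigma_new, Nj

    def _init_params(self, X, mask, rng):
        K = X.shape[1]
        col_mean = np.nanmean(X, axis=0)
        Xf = np.where(mask, X, col_mean)
        k = self.n_components
        if k == 1:
            centers = Xf.mean(axis=0, keepdims=True)
        else:
            centers, _ = kmeans_plusplus(
                Xf, n_clusters=k, random_state=rng.integers(2 ** 31 - 1))
        d = ((Xf[:, None, :] - centers[None]) ** 2).sum(axis=2)
        lab = d.argmin(axis=1)
        pi = np.full(k, 1.0 / k)
        mu = centers.copy()
        Sigma = np.empty((k, K, K))
        base = np.cov(Xf, rowvar=False) + self.ridge * np.eye(K)
        base = np.atleast_2d(base)
        for j in range(k):
            sel = Xf[lab == j]
            if len(sel) > 2 * K:
                Sigma[j] = self._floor_cov(np.cov(sel, rowvar=False)
                                           + self.ridge * np.eye(K))
            else:
                Sigma[j] = base
            pi[j] = max((lab == j).mean(), 1e-3)
        return pi / pi.sum(), mu, Sigma

    def _run_em(self, X, mask, rng):
        if self.means_init is not None:
            k, K = self.n_components, X.shape[1]
            pi = (np.asarray(self.weights_init, float)
                  if self.weights_init is not None else np.full(k, 1.0 / k))
            mu = np.asarray(self.means_init, dtype=float).copy()
            Sigma = (np.asarray(self.covariances_init, dtype=float).copy()
                     if self.covariances_init is not None
                     else np.broadcast_to(np.eye(K), (k, K, K)).copy())
        else:
            pi, mu, Sigma = self._init_params(X, mask, rng)
        groups = [(p, r) for p, r in _patterns(mask)]
        trace = []
        reseeded = False
        ll_prev = -np.inf
        for _ in range(self.max_iter):
            logR, lognorm = self._estep(X, mask, pi, mu, Sigma, groups)
            ll = float(lognorm.sum())
            trace.append(ll)
            R = np.exp(logR)
            pi, mu, Sigma, Nj = self._mstep(X, mask, R, mu, Sigma, groups)
            if (Nj < 1e-8 * len(X)).any():
                if reseeded:
                    raise ComponentCollapseError("component collapsed twice")
                reseeded = True
                dead = np.where(Nj < 1e-8 * len(X))[0]
                col_mean = np.nanmean(X, axis=0)
                Xf = np.where(mask, X, col_mean)
                for j in dead:
                    mu[j] = Xf[rng.integers(len(X))]
                    Sigma[j] = self._floor_cov(np.cov(Xf, rowvar=False)
                                               + np.eye(X.shape[1]))
                    pi[j] = 1.0 / len(pi)
                pi = pi / pi.sum()
                continue
            if ll - ll_prev < self.tol * max(abs(ll), 1.0) and len(trace) > 1:
                break
            ll_prev = ll
        return pi, mu, Sigma, trace

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X, mask = self._prepare(X)
        rng = np.random.default_rng(self.random_state)
        best = None
        n_init = 1 if self.means_init is not None else self.n_init
        for _ in range(n_init):
            try:
                pi, mu, Sigma, trace = self._run_em(X, mask, rng)
            except (np.linalg.LinAlgError, ComponentCollapseError):
                continue
            if best is None or trace[-1] > best[3][-1]:
                best = (pi, mu, Sigma, trace)
        if best is None:
            raise ComponentCollapseError(
                "all EM restarts failed; data may be degenerate for this k")
        pi, mu, Sigma, trace = best
        order = np.argsort(mu[:, 0], kind="stable")
        self.weights_ = pi[order]
        self.means_ = mu[order]
        self.covariances_ = Sigma[order]
        self.loglik_trace_ = np.asarray(trace)
        logR, lognorm = self._estep(X, mask, self.weights_, self.means_,
                                    self.covariances_)
        self.responsibilities_ = np.exp(logR)
        self.entropies_ = entropy(self.responsibilities_)
        self.lower_bound_ = float(lognorm.sum())
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X, mask = self._prepare(X)
        logR, _ = self._estep(X, mask, self.weights_, self.means_,
                              self.covariances_)
        return np.exp(logR)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def score_samples(self, X):
        X, mask = self._prepare(X)
        _, lognorm = self._estep(X, mask, self.weights_, self.means_,
                                 self.covariances_)
        return lognorm

    def score(self, X, y=None):
        return float(self.score_samples(X).mean())

    def _n_parameters(self) -> int:
        K = self.n_features_in_
        return (self.n_components - 1 + self.n_components * K
                + self.n_components * K * (K + 1) // 2)

    def bic(self, X) -> float:
        X = np.asarray(X, dtype=float)
        return (-2.0 * self.score_samples(X).sum()
                + self._n_parameters() * np.log(X.shape[0]))

    def complete_data(self, X) -> np.ndarray:
        """Fill missing coordinates with their conditional expectation under
        each row's most probable component (used for silhouette scoring)."""
        X, mask = self._prepare(X)
        lab = self.predict(X)
        out = X.copy()
        for pat, rows in _patterns(mask):
            o, m = np.where(pat)[0], np.where(~pat)[0]
            if m.size == 0:
                continue
            for j in np.unique(lab[rows]):
                rj = rows[lab[rows] == j]
                Soo = self.covariances_[j][np.ix_(o, o)]
                Smo = self.covariances_[j][np.ix_(m, o)]
                A = np.linalg.solve(Soo, Smo.T).T
                out[np.ix_(rj, m)] = (self.means_[j][m]
                                      + (X[np.ix_(rj, o)] - self.means_[j][o]) @ A.T)
        return out


def fit_mgmm(Z: np.ndarray, k: int, seed: int | None = None,
             max_iter: int = 200, tol: float = 1e-6, **kw) -> MissingDataGMM:
    """Convenience wrapper: fit a ``MissingDataGMM`` with k components."""
    return MissingDataGMM(n_components=k, max_iter=max_iter, tol=tol,
                          random_state=seed, **kw).fit(Z)


def entropy(responsibilities: np.ndarray) -> np.ndarray:
    """Assignment entropy −sum_j p_j ln p_j per row (0 * ln 0 = 0)."""
    p = np.atleast_2d(np.asarray(responsibilities, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    out = -terms.sum(axis=1)
    return out if out.size > 1 else out[0] if responsibilities.ndim == 1 else out


def filter_entropy(model: MissingDataGMM, threshold: float = 0.75
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Hard assignments for the unambiguous rows.

    Returns (retained row indices, cluster labels).  Rows with posterior
    entropy above ``threshold`` are excluded as ambiguous; exact ties in the
    maximum responsibility go to the lower cluster index and are logged.
    """
    R = model.responsibilities_
    ent = model.entropies_
    keep = np.where(ent <= threshold)[0]
    labels = R[keep].argmax(axis=1)
    ties = (R[keep] == R[keep].max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d rows with tied responsibilities assigned to the "
                    "lowest cluster index", int(ties.sum()))
    return keep, labels


@dataclass
class KSelection:
    k: int
    curves: pd.DataFrame          # per (k, replicate): bic, silhouette
    k_bic: int
    k_silhouette: int


def select_k(Z: np.ndarray, k_range=range(2, 11), n_boot: int = 100,
             subsample: float = 0.80, seed: int | None = 0,
             alpha: float = 0.05, **fit_kw) -> KSelection:
    """Choose the number of clusters by a compound BIC / silhouette rule.

    For each k, the mixture is fitted ``n_boot`` times on random
    ``subsample`` fractions of the rows, recording BIC and the silhouette of
    the hard assignments (Euclidean distance on model-completed data).  The
    silhouette tends to be conservative and BIC anticonservative, so: start
    from the silhouette-optimal k; if the BIC optimum is larger, increase k
    until either adding a cluster significantly decreases the silhouette
    (one-sided Welch test on replicate silhouettes at ``alpha``) or the BIC
    optimum is reached.
    """
    Z = np.asarray(Z, dtype=float)
    rng = np.random.default_rng(seed)
    n = Z.shape[0]
    rows = []
    for k in k_range:
        failures = 0
        for b in range(n_boot):
            idx = rng.choice(n, size=max(int(round(subsample * n)), k + 1),
                             replace=False)
            sub = Z[idx]
            try:
                model = MissingDataGMM(
                    n_components=k, random_state=int(rng.integers(2 ** 31 - 1)),
                    **fit_kw).fit(sub)
                labels = model.predict(sub)
                if len(np.unique(labels)) < 2:
                    sil = np.nan
                else:
                    sil = silhouette_score(model.complete_data(sub), labels)
                rows.append({"k": k, "replicate": b, "bic": model.bic(sub),
                             "silhouette": sil})
            except ComponentCollapseError:
                failures += 1
        if failures == n_boot:
            logger.warning("k=%d excluded: every fit collapsed", k)
    curves = pd.DataFrame(rows)
    if curves.empty:
        raise ConfigurationError("no k could be fitted")
    return compound_k_rule(curves, alpha=alpha)


def compound_k_rule(curves: pd.DataFrame, alpha: float = 0.05) -> KSelection:
    """Apply the compound BIC/silhouette decision to per-replicate curves.

    ``curves`` has columns (k, replicate, bic, silhouette).  If the BIC
    optimum exceeds the silhouette optimum, walk upward from the silhouette
    optimum, stopping before any k whose silhouette is significantly lower
    than its predecessor's (one-sided Welch test at ``alpha``) and never past
    the BIC optimum; otherwise keep the silhouette optimum."""
    means = curves.groupby("k").agg(bic=("bic", "mean"),
                                    silhouette=("silhouette", "mean"))
    k_bic = int(means["bic"].idxmin())
    k_sil = int(means["silhouette"].idxmax())
    selected = k_sil
    if k_bic > k_sil:
        ks = sorted(k for k in means.index if k_sil <= k <= k_bic)
        for cur, nxt in zip(ks, ks[1:]):
            s_cur = curves.loc[curves["k"] == cur, "silhouette"].dropna()
            s_nxt = curves.loc[curves["k"] == nxt, "silhouette"].dropna()
            if len(s_cur) > 1 and len(s_nxt) > 1:
                t, p = stats.ttest_ind(s_nxt, s_cur, equal_var=False,
                                       alternative="less")
                if p < alpha:          # significant silhouette drop: stop
                    break
            selected = nxt
            if nxt == k_bic:
                break
    return KSelection(k=selected, curves=curves, k_bic=k_bic,
                      k_silhouette=k_sil)
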