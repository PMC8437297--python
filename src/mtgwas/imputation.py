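"""Conditional-mean imputation of missing Z-scores from local LD, with a
post-imputation neighbourhood quality-control filter.

Within an LD region, the Z-scores of typed and untyped SNPs are jointly
normal with covariance equal to the SNP correlation matrix, so the best
linear predictor of a missing Z is
``Sigma_t,obs (Sigma_obs,obs + lambda I)^-1 z_obs``; the same quadratic form
with the right-hand side replaced by Sigma_obs,t gives the imputation
quality (the fraction of the missing Z's variance explained).  The ridge
term ``lambda`` guards against near-singular LD.
"""

from __future__ import annotations

import logging

import numpy as np

from mtgwas.sumstats import LDPanel, SumstatsPanel

logger = logging.getLogger(__name__)

#: ridge on the observed-observed LD block
DEFAULT_LAMBDA = 0.1
#: minimum imputation quality to accept an imputed Z
DEFAULT_QUALITY = 0.6


def impute_region(z_obs: np.ndarray, obs_idx: np.ndarray, ld: np.ndarray,
                  lam: float = DEFAULT_LAMBDA,
                  quality_threshold: float = DEFAULT_QUALITY,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Impute one trait's missing Z-scores within one region.

    Parameters
    ----------
    z_obs : observed Z values, aligned with ``obs_idx``.
    obs_idx : indices (into the region's SNP list) of the observed SNPs.
    ld : the region's full SNP correlation matrix.

    Returns ``(z_full, quality)`` over all region SNPs: observed entries are
    passed through with quality 1; imputed entries below ``quality_threshold``
    are left NaN (their quality is still reported).
    """
    m = ld.shape[0]
    z_full = np.full(m, np.nan)
    quality = np.zeros(m)
    obs_idx = np.asarray(obs_idx, dtype=int)
    if obs_idx.size == 0:
        logger.warning("region with no observed SNPs; nothing imputed")
        return z_full, quality
    z_full[obs_idx] = z_obs
    quality[obs_idx] = 1.0
    miss_idx = np.setdiff1d(np.arange(m), obs_idx)
    if miss_idx.size == 0:
        return z_full, quality
    S_oo = ld[np.ix_(obs_idx, obs_idx)] + lam * np.eye(obs_idx.size)
    S_mo = ld[np.ix_(miss_idx, obs_idx)]
    W = np.linalg.solve(S_oo, S_mo.T).T          # (n_miss, n_obs)
    zhat = W @ np.asarray(z_obs, dtype=float)
    q = np.einsum("ij,ij->i", W, S_mo)
    quality[miss_idx] = q
    accepted = q >= quality_threshold
    z_full[miss_idx[accepted]] = zhat[accepted]
    return z_full, quality


def impute_panel(panel: SumstatsPanel, ld: LDPanel,
                 lam: float = DEFAULT_LAMBDA,
                 quality_threshold: float = DEFAULT_QUALITY) -> SumstatsPanel:
    """Impute every trait and region of a panel; observed entries are never
    altered, newly filled entries are flagged in ``imputed_mask`` and given
    the trait's median sample size."""
    out = panel.copy()
    pos = {s: i for i, s in enumerate(panel.snps["snp_id"])}
    for ids, mat in zip(ld.region_snps, ld.matrices):
        rows = np.array([pos[s] for s in ids if s in pos], dtype=int)
        keep = np.array([s in pos for s in ids], dtype=bool)
        if rows.size == 0:
            continue
        mat = mat[np.ix_(keep, keep)]
        for k in range(panel.n_traits):
            z = panel.Z[rows, k]
            obs = ~np.isnan(z)
            if obs.all() or not obs.any():
                continue
            z_full, _ = impute_region(z[obs], np.where(obs)[0], mat, lam,
                                      quality_threshold)
            filled = np.isnan(z) & ~np.isnan(z_full)
            out.Z[rows[filled], k] = z_full[filled]
            out.imputed_mask[rows[filled], k] = True
            med_n = np.nanmedian(panel.N[:, k])
            out.N[rows[filled], k] = med_n
    return out


def post_imputation_qc(panel: SumstatsPanel, ld: LDPanel, pvalues: np.ndarray,
                       p_signif: float = 1e-8, p_neighbor: float = 1e-6,
                       r2_neighbor: float = 0.2) -> np.ndarray:
    """Flag significant SNPs not supported by their LD neighbourhood.

    A SNP with p < ``p_signif`` is kept only if at least one distinct SNP in
    LD with it (r^2 >= ``r2_neighbor``, same region) has p < ``p_neighbor``.
    Returns a boolean keep-mask over the panel's SNPs (non-significant SNPs
    are always kept; the filter only removes unsupported hits).
    """
    pvalues = np.asarray(pvalues, dtype=float)
    keep = np.ones(panel.n_snps, dtype=bool)
    pos = {s: i for i, s in enumerate(panel.snps["snp_id"])}
    for ids, mat in zip(ld.region_snps, ld.matrices):
        present = [(j, pos[s]) for j, s in enumerate(ids) if s in pos]
        if not present:
            continue
        jj = np.array([j for j, _ in present])
        rows = np.array([r for _, r in present])
        p = pvalues[rows]
        sig = np.nan_to_num(p, nan=1.0) < p_signif
        if not sig.any():
            continue
        r2 = mat[np.ix_(jj, jj)] ** 2
        near = np.nan_to_num(p, nan=1.0) < p_neighbor
        for a in np.where(sig)[0]:
            friends = (r2[a] >= r2_neighbor) & near
            friends[a] = False
            if not friends.any():
                keep[rows[a]] = False
    return keep
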