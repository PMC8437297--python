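"""Preprocessing of per-trait summary statistics: Z-score derivation from
signed statistics and p-values, sample-size inference, and the low-sample-size
filter applied before joint testing."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from mtgwas.sumstats import ConfigurationError, SumstatsPanel, SumstatsTable

logger = logging.getLogger(__name__)

#: smallest p-value substituted for p == 0; far beyond the 1e-8 decision
#: threshold, so the substitution cannot change any call
P_FLOOR = 1e-300


def derive_z(table: SumstatsTable, p_floor: float = P_FLOOR,
             overwrite: bool = False) -> SumstatsTable:
    """Derive two-sided Z-scores: z = sign(effect) * Phi^-1(1 - p/2).

    The sign comes from ``beta`` (or an existing ``z``); rows without a sign
    source keep ``z`` missing.  Existing z values are preserved unless
    ``overwrite`` is set; when both z and beta/se are present but inconsistent
    (|z - beta/se| > 0.1) the p-derived value wins and the conflict is logged.
    """
    df = table.df.copy()
    p = df["pvalue"].values.astype(float)
    zero = p == 0
    if zero.any():
        logger.warning("%d rows with p == 0; flooring at %g", int(zero.sum()), p_floor)
        p = np.where(zero, p_floor, p)
    sign = np.sign(df["beta"].values.astype(float))
    no_beta = np.isnan(sign) | (sign == 0)
    sign = np.where(no_beta, np.sign(df["z"].values.astype(float)), sign)
    magnitude = stats.norm.isf(p / 2.0)
    z_new = sign * magnitude
    have = ~np.isnan(z_new) & ~np.isnan(p)
    old = df["z"].values.astype(float)
    if not overwrite:
        ratio = df["beta"].values / df["se"].values
        conflict = have & ~np.isnan(old) & ~np.isnan(ratio) & (np.abs(old - ratio) > 0.1)
        if conflict.any():
            logger.warning("%d rows where z disagrees with beta/se; "
                           "using p-derived z", int(conflict.sum()))
        have = have & (np.isnan(old) | conflict)
    df["z"] = np.where(have, z_new, old)
    return SumstatsTable(df, trait=table.trait, validate=False)


def infer_sample_size(table: SumstatsTable,
                      freq_source: dict[str, float] | None = None) -> SumstatsTable:
    """Fill missing per-SNP sample sizes with the proxy 1 / (se^2 * 2f(1-f)).

    ``2f(1-f)`` is the variance of an allele-dosage genotype at coded-allele
    frequency ``f``; for a linear model the proxy targets N * var(residual),
    and for a case/control logit model it is proportional to N p (1-p).
    Observed n values are never touched; rows whose frequency falls outside
    (0, 1) keep n missing.  A boolean ``n_inferred`` marker column records
    which rows were filled.
    """
    df = table.df.copy()
    f = df["freq"].values.astype(float)
    if freq_source is not None:
        ref_f = df["snp_id"].map(freq_source).values.astype(float)
        f = np.where(np.isnan(f), ref_f, f)
    se = df["se"].values.astype(float)
    valid = (f > 0) & (f < 1) & (se > 0)
    sigma_g2 = 2.0 * f * (1.0 - f)
    with np.errstate(divide="ignore", invalid="ignore"):
        proxy = 1.0 / (se ** 2 * sigma_g2)
    proxy = np.where(valid, proxy, np.nan)
    missing = df["n"].isna().values
    df["n"] = np.where(missing, proxy, df["n"].values)
    df["n_inferred"] = missing & ~np.isnan(proxy)
    out = SumstatsTable(df.drop(columns=["n_inferred"]), trait=table.trait,
                        validate=False)
    out.df["n_inferred"] = df["n_inferred"].values
    return out


def filter_low_n(panel: SumstatsPanel, fraction: float = 0.70,
                 robust_max: bool = True) -> SumstatsPanel:
    """Mask per-trait entries whose sample size falls below ``fraction`` of the
    trait's maximum sample size.

    Mixing SNPs analysed in very different numbers of samples makes a single
    genome-wide null covariance wrong for the small-n SNPs, so such entries
    are set missing rather than rescaled.  With ``robust_max`` the per-trait
    reference is the 99.9th percentile of n instead of the literal maximum,
    which resists single-row typos.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    out = panel.copy()
    for k in range(panel.n_traits):
        n = panel.N[:, k]
        obs = ~np.isnan(n)
        if not obs.any():
            continue
        ref = np.nanpercentile(n, 99.9) if robust_max else np.nanmax(n)
        low = obs & (n < fraction * ref)
        out.Z[low, k] = np.nan
        out.N[low, k] = np.nan
        out.imputed_mask[low, k] = False
    return out
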