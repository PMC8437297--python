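"""Region-level signal extraction, greedy LD clumping, and classification of
associations as new (multitrait-only) versus already detectable univariately."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mtgwas.sumstats import ConfigurationError, LDPanel, SumstatsPanel

logger = logging.getLogger(__name__)

GENOME_WIDE = 1e-8


def region_minp(joint_p: np.ndarray, univ_p: np.ndarray,
                region_index: np.ndarray) -> pd.DataFrame:
    """Per-region minima of the joint and univariate p-value tracks.

    ``region_index`` assigns every SNP to exactly one region (see
    ``RegionSet.assign``); a −1 entry raises, listing the offenders.
    Regions with no SNPs are absent from the output.
    """
    region_index = np.asarray(region_index)
    if (region_index < 0).any():
        bad = np.where(region_index < 0)[0]
        raise ConfigurationError(
            f"{bad.size} SNPs outside all regions (first offenders: {bad[:5].tolist()})")
    df = pd.DataFrame({"region": region_index,
                       "joint_p": np.nan_to_num(joint_p, nan=1.0),
                       "univ_p": np.nan_to_num(univ_p, nan=1.0)})
    out = df.groupby("region").min()
    out.columns = ["min_joint_p", "min_univ_p"]
    return out.reset_index()


def classify_novel(minima: pd.DataFrame, joint_threshold: float = GENOME_WIDE,
                   univ_threshold: float = GENOME_WIDE) -> pd.DataFrame:
    """Label each region by which analyses reach significance.

    ``multitrait_only`` marks newly detected regions: joint p below the
    genome-wide threshold while every univariate p stays above it.
    """
    out = minima.copy()
    j = out["min_joint_p"] < joint_threshold
    u = out["min_univ_p"] < univ_threshold
    out["novelty"] = np.select(
        [j & ~u, ~j & u, j & u], ["multitrait_only", "univariate_only", "both"],
        default="neither")
    return out


@dataclass
class Clump:
    lead: int                  # index of the lead SNP
    members: np.ndarray        # indices absorbed by the lead (lead included)


def clump(pvalues: np.ndarray, ld: LDPanel, snp_ids: list[str],
          pos: np.ndarray | None = None, p1: float = GENOME_WIDE,
          r2: float = 0.2) -> list[Clump]:
    """Greedy LD clumping in the PLINK convention.

    Repeatedly take the smallest-p SNP with p < ``p1`` not yet absorbed and
    absorb every SNP with squared correlation >= ``r2`` to it (LD across
    regions is treated as zero).  Ties on p are broken by genomic position
    then id.  Leads are returned in selection order.
    """
    p = np.nan_to_num(np.asarray(pvalues, dtype=float), nan=1.0)
    n = len(p)
    pos = np.asarray(pos) if pos is not None else np.arange(n)
    idx_of = {s: i for i, s in enumerate(snp_ids)}
    neighbors: dict[int, np.ndarray] = {}
    for ids, mat in zip(ld.region_snps, ld.matrices):
        present = [(j, idx_of[s]) for j, s in enumerate(ids) if s in idx_of]
        if not present:
            continue
        jj = np.array([a for a, _ in present])
        rows = np.array([b for _, b in present])
        r2mat = mat[np.ix_(jj, jj)] ** 2
        for a in range(len(rows)):
            neighbors[rows[a]] = rows[r2mat[a] >= r2]
    order = sorted(np.where(p < p1)[0],
                   key=lambda i: (p[i], pos[i], str(snp_ids[i])))
    absorbed = np.zeros(n, dtype=bool)
    clumps: list[Clump] = []
    for i in order:
        if absorbed[i]:
            continue
        members = neighbors.get(i, np.array([i]))
        members = members[~absorbed[members]]
        absorbed[members] = True
        absorbed[i] = True
        clumps.append(Clump(lead=int(i), members=np.union1d(members, [i])))
    return clumps


def select_cluster_snps(panel: SumstatsPanel, p_tracks: dict[str, np.ndarray],
                        ld: LDPanel, threshold: float = GENOME_WIDE,
                        r2: float = 0.2,
                        min_observed: float = 0.60) -> np.ndarray:
    """Pick one representative SNP per independent association for clustering.

    SNPs passing any of the provided p-value tracks (typically the minimum
    univariate, the ICA sumZ and the omnibus p) at ``threshold`` are clumped
    at (p1=threshold, r2); each clump's representative is its smallest-p
    member whose Z-score profile is at least ``min_observed`` observed.
    Clumps with no sufficiently observed member are dropped with a warning.
    Returns panel row indices of the representatives.
    """
    tracks = np.column_stack([np.nan_to_num(v, nan=1.0)
                              for v in p_tracks.values()])
    best_p = tracks.min(axis=1)
    clumps = clump(best_p, ld, list(panel.snps["snp_id"]),
                   pos=panel.snps["pos"].values, p1=threshold, r2=r2)
    observed_frac = panel.mask.mean(axis=1)
    reps = []
    for c in clumps:
        members = c.members[np.argsort(best_p[c.members], kind="stable")]
        ok = members[observed_frac[members] >= min_observed]
        if ok.size == 0:
            logger.warning("clump led by %s dropped: no member with >= %.0f%% "
                           "observed values", panel.snps["snp_id"].iat[c.lead],
                           100 * min_observed)
            continue
        reps.append(int(ok[0]))
    return np.asarray(sorted(set(reps)), dtype=int)
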