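"""Core containers and IO: per-trait summary statistics, multi-trait panels,
LD reference, and cross-trait allele harmonization.

Conventions: positions are 1-based; region intervals are half-open
``[start, end)``; missing values are NaN backed by an explicit mask, never a
sentinel number; alleles are single upper-case nucleotides.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: strand-ambiguous pairs: complement equals the swap, orientation undecidable
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: canonical column order for sumstats tables
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "coded_allele", "other_allele",
    "z", "beta", "se", "pvalue", "n", "freq",
]
_REQUIRED = ["snp_id", "chrom", "pos", "coded_allele", "other_allele"]


class InputError(ValueError):
    """Raised when an input file has no usable content."""


class ConfigurationError(ValueError):
    """Raised when arguments or column maps are inconsistent."""


# ---------------------------------------------------------------------------
# SumstatsTable


class SumstatsTable:
    """One trait's GWAS summary statistics.

    Wraps a DataFrame with the canonical columns (``snp_id, chrom, pos,
    coded_allele, other_allele, z, beta, se, pvalue, n, freq``); optional
    numeric columns may be NaN.  Validation drops duplicate SNP ids, rejects
    non-ACGT alleles and non-positive positions, and checks that the signs of
    ``z`` and ``beta`` agree where both are present.
    """

    def __init__(self, df: pd.DataFrame, trait: str = "trait", validate: bool = True):
        df = df.copy()
        for col in SUMSTATS_COLUMNS:
            if col not in df.columns:
                if col in _REQUIRED:
                    raise ConfigurationError(f"missing required column {col!r}")
                df[col] = np.nan
        df = df[SUMSTATS_COLUMNS]
        if validate:
            df = self._validate(df)
        self.df = df.reset_index(drop=True)
        self.trait = trait

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        n0 = len(df)
        dup = df["snp_id"].duplicated(keep="first")
        if dup.any():
            logger.warning("dropping %d duplicated snp_id rows", int(dup.sum()))
            df = df[~dup]
        alleles_ok = df["coded_allele"].isin(_VALID_ALLELES) & df[
            "other_allele"
        ].isin(_VALID_ALLELES)
        pos_ok = pd.to_numeric(df["pos"], errors="coerce") > 0
        keep = alleles_ok & pos_ok
        if (~keep).any():
            logger.warning("dropping %d rows with invalid alleles/positions", int((~keep).sum()))
            df = df[keep]
        if len(df) == 0 and n0 > 0:
            raise InputError("no valid rows after validation")
        both = df["z"].notna() & df["beta"].notna()
        bad = both & (np.sign(df["z"]) * np.sign(df["beta"]) < 0)
        if bad.any():
            raise ConfigurationError(
                f"{int(bad.sum())} rows where sign(z) != sign(beta)"
            )
        df = df.copy()
        df["pos"] = df["pos"].astype(np.int64)
        for col in ["z", "beta", "se", "pvalue", "n", "freq"]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        return df

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SumstatsTable(trait={self.trait!r}, n_snps={len(self)})"


def read_sumstats(path: str, column_map: dict[str, str] | None = None,
                  trait: str | None = None) -> SumstatsTable:
    """Read a headered whitespace/tab-delimited summary-statistics file.

    ``column_map`` maps canonical names to file column names, e.g.
    ``{"snp_id": "SNP", "pvalue": "P"}``; canonical names already present in
    the header need not be mapped.  Rows whose required fields fail to parse
    are dropped and counted in the log; "NA" in optional columns yields a
    missing value, not a dropped row.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str}, na_values=["NA", "NaN", ""])
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise ConfigurationError(f"mapped columns absent from file: {missing}")
        df = df.rename(columns=rename)
    absent = [c for c in _REQUIRED if c not in df.columns]
    if absent:
        raise ConfigurationError(f"required columns missing: {absent}")
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for a in ("coded_allele", "other_allele"):
        df[a] = df[a].astype(str).str.upper()
    table = SumstatsTable(df, trait=trait or os.path.basename(path))
    if len(table) == 0:
        raise InputError(f"{path}: zero valid rows")
    return table


def write_sumstats(table: SumstatsTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


# ---------------------------------------------------------------------------
# RegionSet


@dataclass
class RegionSet:
    """Ordered LD blocks as half-open ``[start, end)`` intervals per chromosome."""

    regions: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self):
        df = self.regions.reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            raise ConfigurationError("region with end <= start")
        for _, sub in df.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ConfigurationError("overlapping regions within a chromosome")
        self.regions = df

    def __len__(self) -> int:
        return len(self.regions)

    def assign(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Region index for each (chrom, pos); −1 where no region contains it."""
        out = np.full(len(chrom), -1, dtype=np.int64)
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos)
        for c, sub in self.regions.groupby("chrom"):
            m = chrom == c
            if not m.any():
                continue
            starts, ends = sub["start"].values, sub["end"].values
            order = np.argsort(starts)
            starts, ends, idx = starts[order], ends[order], sub.index.values[order]
            j = np.searchsorted(starts, pos[m], side="right") - 1
            ok = (j >= 0) & (pos[m] < ends[np.clip(j, 0, None)])
            res = np.where(ok, idx[np.clip(j, 0, None)], -1)
            out[m] = res
        return out

    @classmethod
    def read_bed(cls, path: str) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end"], dtype={"chrom": str})
        return cls(df)

    def write_bed(self, path: str) -> None:
        self.regions.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# LDPanel


@dataclass
class LDPanel:
    """Per-region SNP correlation matrices with an aligned SNP reference index.

    ``snps`` carries the reference SNP frame (snp_id, chrom, pos,
    coded_allele, other_allele) used for harmonization; ``matrices[i]`` is
    the correlation matrix of the SNPs of region ``i`` (ids in
    ``region_snps[i]``, a subset of ``snps.snp_id``).
    """

    regions: RegionSet
    region_snps: list[list[str]]
    matrices: list[np.ndarray]
    snps: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for ids, mat in zip(self.region_snps, self.matrices):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(ids), len(ids)):
                raise ConfigurationError("LD matrix shape mismatch with SNP list")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ConfigurationError("LD matrix not symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
                raise ConfigurationError("LD matrix diagonal must be 1")
            if np.linalg.eigvalsh(mat).min() < -1e-6:
                raise ConfigurationError("LD matrix not positive semi-definite")
        if self.snps is None:
            rows = []
            for r, ids in enumerate(self.region_snps):
                reg = self.regions.regions.iloc[r]
                for k, s in enumerate(ids):
                    rows.append((s, reg["chrom"], int(reg["start"]) + k + 1, "A", "G"))
            self.snps = pd.DataFrame(
                rows, columns=["snp_id", "chrom", "pos", "coded_allele", "other_allele"]
            )

    @property
    def n_regions(self) -> int:
        return len(self.matrices)

    def region_of(self, snp_id: str) -> int:
        for r, ids in enumerate(self.region_snps):
            if snp_id in ids:
                return r
        return -1

    def pairwise_r2(self, ids_a: list[str], ids_b: list[str]) -> np.ndarray:
        """Squared correlation between two SNP id lists; 0 across regions."""
        out = np.zeros((len(ids_a), len(ids_b)))
        for ids, mat in zip(self.region_snps, self.matrices):
            lut = {s: i for i, s in enumerate(ids)}
            ia = [(k, lut[s]) for k, s in enumerate(ids_a) if s in lut]
            ib = [(k, lut[s]) for k, s in enumerate(ids_b) if s in lut]
            for ka, pa in ia:
                for kb, pb in ib:
                    out[ka, kb] = mat[pa, pb] ** 2
        return out

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        self.regions.write_bed(os.path.join(directory, "regions.bed"))
        self.snps.to_csv(os.path.join(directory, "snps.tsv"), sep="\t", index=False)
        sidecar = []
        for r, (ids, mat) in enumerate(zip(self.region_snps, self.matrices)):
            fname = f"region_{r:05d}.txt"
            np.savetxt(os.path.join(directory, fname), mat, fmt="%.17g")
            sidecar.append({"region": r, "file": fname, "snp_ids": list(ids)})
        with open(os.path.join(directory, "ld_index.json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, directory: str) -> "LDPanel":
        regions = RegionSet.read_bed(os.path.join(directory, "regions.bed"))
        snps = pd.read_csv(os.path.join(directory, "snps.tsv"), sep="\t",
                           dtype={"snp_id": str, "chrom": str})
        with open(os.path.join(directory, "ld_index.json")) as fh:
            sidecar = json.load(fh)
        ids, mats = [], []
        for entry in sorted(sidecar, key=lambda e: e["region"]):
            ids.append(list(entry["snp_ids"]))
            mats.append(np.loadtxt(os.path.join(directory, entry["file"]), ndmin=2))
        return cls(regions, ids, mats, snps)


# ---------------------------------------------------------------------------
# SumstatsPanel


class SumstatsPanel:
    """Aligned SNP × trait matrix of Z-scores with explicit missingness.

    Attributes
    ----------
    snps : DataFrame with snp_id, chrom, pos, coded_allele, other_allele.
    traits : list of K trait names (K >= 2).
    Z, N : (n_snps, K) float arrays, NaN where missing.
    imputed_mask : (n_snps, K) bool array flagging imputed Z entries.
    """

    def __init__(self, snps: pd.DataFrame, traits: list[str], Z: np.ndarray,
                 N: np.ndarray, imputed_mask: np.ndarray | None = None):
        if len(traits) < 2:
            raise ConfigurationError("a panel needs at least two traits")
        self.snps = snps.reset_index(drop=True)
        self.traits = list(traits)
        self.Z = np.asarray(Z, dtype=float)
        self.N = np.asarray(N, dtype=float)
        if self.Z.shape != (len(self.snps), len(traits)):
            raise ConfigurationError("Z shape mismatch")
        self.imputed_mask = (
            np.zeros_like(self.Z, dtype=bool) if imputed_mask is None
            else np.asarray(imputed_mask, dtype=bool)
        )

    @property
    def mask(self) -> np.ndarray:
        """True where Z is observed."""
        return ~np.isnan(self.Z)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def copy(self) -> "SumstatsPanel":
        return SumstatsPanel(self.snps.copy(), list(self.traits), self.Z.copy(),
                             self.N.copy(), self.imputed_mask.copy())

    def to_frame(self) -> pd.DataFrame:
        z = pd.DataFrame(self.Z, columns=[f"z_{t}" for t in self.traits])
        n = pd.DataFrame(self.N, columns=[f"n_{t}" for t in self.traits])
        return pd.concat([self.snps, z, n], axis=1)

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.17g", na_rep="NA")

    @classmethod
    def load(cls, path: str) -> "SumstatsPanel":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str},
                         na_values=["NA"])
        traits = [c[2:] for c in df.columns if c.startswith("z_")]
        Z = df[[f"z_{t}" for t in traits]].values
        N = df[[f"n_{t}" for t in traits]].values
        snps = df[["snp_id", "chrom", "pos", "coded_allele", "other_allele"]]
        return cls(snps, traits, Z, N)


def _orient(coded, other, ref_coded, ref_other):
    """Return +1 (same orientation), −1 (swapped: flip sign), or 0 (no match).

    Strand flips are resolved by complementing before matching.
    """
    for c, o, sgn in ((coded, other, 1),
                      (_COMPLEMENT.get(coded), _COMPLEMENT.get(other), 1)):
        if c == ref_coded and o == ref_other:
            return sgn
        if c == ref_other and o == ref_coded:
            return -sgn
    return 0


def harmonize_panel(tables: list[SumstatsTable],
                    reference: LDPanel | pd.DataFrame) -> SumstatsPanel:
    """Align per-trait tables to a reference SNP frame.

    SNPs are restricted to the reference; per trait, allele-swapped records
    get their ``z``/``beta`` signs flipped and ``freq`` replaced by ``1−freq``,
    strand flips are complemented before matching, and unmatched orientations
    are left missing.  The reference must contain no strand-ambiguous
    (A/T, C/G) SNPs.
    """
    ref = reference.snps if isinstance(reference, LDPanel) else reference
    amb = [
        (c, o) in _AMBIGUOUS
        for c, o in zip(ref["coded_allele"], ref["other_allele"])
    ]
    if any(amb):
        raise ConfigurationError(
            f"reference contains {sum(amb)} strand-ambiguous SNPs; "
            "exclude A/T and C/G pairs before harmonization"
        )
    ref = ref.reset_index(drop=True)
    idx = {s: i for i, s in enumerate(ref["snp_id"])}
    K = len(tables)
    Z = np.full((len(ref), K), np.nan)
    N = np.full((len(ref), K), np.nan)
    traits = []
    for k, table in enumerate(tables):
        traits.append(table.trait)
        df = table.df
        for row in df.itertuples(index=False):
            i = idx.get(row.snp_id)
            if i is None:
                continue
            sgn = _orient(row.coded_allele, row.other_allele,
                          ref["coded_allele"].iat[i], ref["other_allele"].iat[i])
            if sgn == 0:
                continue
            if not np.isnan(row.z):
                Z[i, k] = sgn * row.z
            if row.n is not None and not np.isnan(row.n):
                N[i, k] = row.n
    return SumstatsPanel(ref[["snp_id", "chrom", "pos", "coded_allele",
                              "other_allele"]], traits, Z, N)
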