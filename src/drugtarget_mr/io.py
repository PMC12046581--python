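"""Reading, validating and writing summary-statistic tables, LD matrices and gene regions.

All tables are tab-delimited UTF-8 text with a single header line and ``NA``
for missing values.  Coordinates are 1-based inclusive, the convention of
GWAS summary files.  Alleles are assumed to be reported on the forward
strand throughout; no strand flipping is ever attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Structural problem with an input file (missing column, non-square matrix)."""


class ValidationError(ValueError):
    """Content violates an invariant (duplicate ids, out-of-range correlation)."""


#: canonical summary-statistic column order
SUMMARY_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_cases",
]

_NUMERIC = {"pos": int, "eaf": float, "beta": float, "se": float,
            "pval": float, "n": float, "n_cases": float}


@dataclass
class SummaryTable:
    """Per-variant association records for one trait.

    ``df`` holds the canonical columns (:data:`SUMMARY_COLUMNS`); ``beta`` is
    the additive effect per copy of ``effect_allele`` in ``trait_units``
    (mmHg for SBP, log-odds for binary outcomes, expression SD for eQTLs).
    ``rejected_rows`` records (0-based input row, reason) for rows that
    failed validation on read; accepted + rejected always equals input rows.
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame
    trait_units: str = ""
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing mandatory columns: {missing}")
        dup = self.df["snp_id"][self.df["snp_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate snp_id: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def subset(self, mask_or_ids) -> "SummaryTable":
        """New table restricted to a boolean mask or an iterable of snp_ids, order preserved."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and (
            len(mask_or_ids) == len(self.df)
            and pd.api.types.is_bool_dtype(np.asarray(mask_or_ids))
        ):
            sub = self.df.loc[np.asarray(mask_or_ids)]
        else:
            keep = set(mask_or_ids)
            sub = self.df.loc[self.df["snp_id"].isin(keep)]
        return SummaryTable(self.trait_name, self.trait_type,
                            sub.reset_index(drop=True), self.trait_units)


@dataclass
class LDMatrix:
    """Signed pairwise correlation matrix over an ordered SNP list."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise FormatError(
                f"LD matrix shape {self.r.shape} does not match {m} SNP ids")
        if np.abs(self.r - self.r.T).max(initial=0.0) > 1e-8:
            raise ValidationError("LD matrix not symmetric within 1e-8")
        if np.abs(np.diag(self.r) - 1.0).max(initial=0.0) > 1e-8:
            raise ValidationError("LD matrix diagonal must be 1")
        if np.abs(self.r).max(initial=0.0) > 1 + 1e-8:
            raise ValidationError("|r| exceeds 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} absent from LD matrix") from None

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def submatrix(self, snp_ids: Iterable[str]) -> "LDMatrix":
        ids = list(snp_ids)
        idx = [self.index_of(s) for s in ids]
        return LDMatrix(ids, self.r[np.ix_(idx, idx)])


@dataclass
class GeneRegion:
    """A gene interval plus a symmetric flank, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene}: start > end")
        if self.flank_bp < 0:
            raise ValidationError(f"{self.gene}: negative flank")

    def contains(self, chrom: str, pos: int) -> bool:
        return (str(chrom) == str(self.chrom)
                and self.start - self.flank_bp <= pos <= self.end + self.flank_bp)

    def with_flank(self, flank_bp: int) -> "GeneRegion":
        return GeneRegion(self.gene, self.chrom, self.start, self.end, flank_bp)


def _row_problem(row: pd.Series) -> str | None:
    """Reason a row violates the per-variant invariants, or None if it is valid."""
    if pd.isna(row["snp_id"]) or str(row["snp_id"]) == "":
        return "missing snp_id"
    for col in ("beta", "se", "pval", "pos", "n"):
        if pd.isna(row[col]):
            return f"missing {col}"
    if row["se"] <= 0:
        return "nonpositive SE"
    if not (0 < row["pval"] <= 1):
        return "pval outside (0,1]"
    if not pd.isna(row["eaf"]) and not (0 <= row["eaf"] <= 1):
        return "eaf outside [0,1]"
    if row["n"] <= 0:
        return "nonpositive n"
    if not pd.isna(row["n_cases"]) and row["n_cases"] <= 0:
        return "nonpositive n_cases"
    ea, oa = str(row["effect_allele"]), str(row["other_allele"])
    if ea == "" or oa == "" or ea == "nan" or oa == "nan":
        return "missing allele"
    if ea == oa:
        return "effect_allele equals other_allele"
    return None


def validate_summary_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Split a raw frame into (accepted rows, [(input row, reason), ...]).

    Total: every input row lands in exactly one of the two outputs.
    """
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    keep, rejected = [], []
    for i, (_, row) in enumerate(df.iterrows()):
        reason = _row_problem(row)
        if reason is None:
            keep.append(i)
        else:
            rejected.append((i, reason))
    return df.iloc[keep].reset_index(drop=True), rejected


def read_summary_table(path: str | Path, trait_name: str = "trait",
                       trait_type: str = "quantitative",
                       trait_units: str = "") -> SummaryTable:
    """Read a canonical summary-statistic TSV.

    Rows violating the per-variant invariants are dropped and recorded in
    ``rejected_rows`` with a reason; a missing mandatory column raises
    :class:`FormatError`, duplicated snp_ids raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str,
                                            "effect_allele": str,
                                            "other_allele": str},
                     na_values=["NA"], keep_default_na=False)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    df = df[SUMMARY_COLUMNS]
    for col, typ in _NUMERIC.items():
        df[col] = pd.to_numeric(df[col], errors="coerce")
    accepted, rejected = validate_summary_frame(df)
    accepted["pos"] = accepted["pos"].astype(int)
    return SummaryTable(trait_name, trait_type, accepted, trait_units,
                        rejected_rows=rejected)


def write_summary_table(table: SummaryTable, path: str | Path) -> None:
    """Write the canonical TSV; missing optional fields become ``NA``."""
    out = table.df[SUMMARY_COLUMNS].copy()
    # n and n_cases are integers when present
    for col in ("n", "n_cases"):
        out[col] = out[col].map(
            lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a tab-delimited square correlation matrix whose first row is the SNP ids."""
    df = pd.read_csv(path, sep="\t")
    snp_ids = [str(c) for c in df.columns]
    r = df.to_numpy(dtype=float)
    if r.shape[0] != r.shape[1]:
        raise FormatError(
            f"{path}: LD matrix is {r.shape[0]}x{r.shape[1]}, not square")
    return LDMatrix(snp_ids, r)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, columns=ld.snp_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_gene_regions(path: str | Path, flank_bp: int = 0) -> dict[str, GeneRegion]:
    """Read a gene-region TSV (columns gene, chrom, start, end) keyed by gene symbol."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    regions = {}
    for _, row in df.iterrows():
        regions[row["gene"]] = GeneRegion(row["gene"], row["chrom"],
                                          int(row["start"]), int(row["end"]),
                                          flank_bp)
    return regions


def write_gene_regions(regions: Iterable[GeneRegion], path: str | Path) -> None:
    rows = [{"gene": g.gene, "chrom": g.chrom, "start": g.start, "end": g.end}
            for g in regions]
    pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False)
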