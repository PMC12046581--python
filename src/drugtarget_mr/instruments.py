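"""Instrument selection: significance filtering, region restriction, LD clumping,
and instrument-strength diagnostics (per-SNP F, variance explained).

Drug-target instruments are SNPs within a flanked gene window that pass
genome-wide significance for the exposure and survive greedy LD clumping at
r^2 < 0.1; genome-wide exposure instruments use the stricter r^2 < 0.001.
Clumping operates on a user-supplied LD matrix only — there is no
reference-panel lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneRegion, LDMatrix, SummaryTable


@dataclass
class InstrumentSet:
    """Clumped instruments for one exposure (a drug-target gene or genome-wide)."""

    exposure_name: str
    target_gene: str  # gene symbol or "genome-wide"
    snp_ids: list[str]
    r2_threshold: float
    p_threshold: float | None = None
    per_snp_f: list[float] = field(default_factory=list)
    r2_explained: float | None = None
    table: SummaryTable | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def filter_significant(table: SummaryTable, p_threshold: float) -> SummaryTable:
    """Keep records with pval < p_threshold, order preserved."""
    return table.subset((table.df["pval"] < p_threshold).to_numpy())


def restrict_to_region(table: SummaryTable, region: GeneRegion) -> SummaryTable:
    """Keep records on region.chrom with start-flank <= pos <= end+flank."""
    df = table.df
    mask = ((df["chrom"].astype(str) == str(region.chrom))
            & (df["pos"] >= region.start - region.flank_bp)
            & (df["pos"] <= region.end + region.flank_bp))
    return table.subset(mask.to_numpy())


def per_snp_f(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F statistic, F = (beta/se)^2."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def variance_explained(table: SummaryTable) -> float:
    """Exposure variance explained by the (clumped) instruments.

    Per-SNP R^2 = z^2 / (z^2 + n - 2) with z = beta/se, summed over SNPs;
    valid for approximately independent instruments.
    """
    df = table.df
    if df["n"].isna().any():
        bad = df.loc[df["n"].isna(), "snp_id"].tolist()
        raise ValueError(f"sample size n missing for {bad}")
    if len(df) == 0:
        return 0.0
    z2 = (df["beta"] / df["se"]) ** 2
    return float((z2 / (z2 + df["n"] - 2)).sum())


def aggregate_f(r2: float, n: float, n_snps: int) -> float:
    """Regression F over J instruments: ((n - J - 1)/J) * R^2/(1 - R^2)."""
    if n_snps < 1:
        raise ValueError("need at least one instrument")
    return ((n - n_snps - 1) / n_snps) * (r2 / (1.0 - r2))


def _clump_order(df: pd.DataFrame) -> np.ndarray:
    """Total retention priority: p ascending, ties by (chrom, pos, snp_id)."""
    key = df[["pval", "chrom", "pos", "snp_id"]].copy()
    key["chrom"] = key["chrom"].astype(str)
    return key.sort_values(["pval", "chrom", "pos", "snp_id"],
                           kind="mergesort").index.to_numpy()


def greedy_clump(table: SummaryTable, ld: LDMatrix, r2_threshold: float,
                 exposure_name: str | None = None,
                 target_gene: str = "genome-wide",
                 p_threshold: float | None = None) -> InstrumentSet:
    """Greedy LD clumping: repeatedly retain the most significant remaining SNP
    and discard all remaining SNPs with r^2 >= r2_threshold to it.

    Output order is retention order; invariant to the input row order
    because priority ties break on (chrom, pos, snp_id).  Every table SNP
    must be present in ``ld`` (cross-block r^2 is taken as 0 only when the
    caller supplies block-diagonal LD explicitly).
    """
    df = table.df.reset_index(drop=True)
    for s in df["snp_id"]:
        ld.index_of(s)  # raises naming the missing SNP
    order = _clump_order(df)
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    snp_pos = {s: i for i, s in enumerate(df["snp_id"])}
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        li = ld.index_of(df.at[i, "snp_id"])
        for j in np.flatnonzero(alive):
            lj = ld.index_of(df.at[j, "snp_id"])
            if ld.r[li, lj] ** 2 >= r2_threshold:
                alive[j] = False
    kept_ids = [df.at[i, "snp_id"] for i in kept]
    sub = df.iloc[kept].reset_index(drop=True)
    kept_table = SummaryTable(table.trait_name, table.trait_type, sub,
                              table.trait_units)
    f_stats = [per_snp_f(b, s) for b, s in zip(sub["beta"], sub["se"])]
    r2_exp = None
    if not sub["n"].isna().any():
        r2_exp = variance_explained(kept_table)
    return InstrumentSet(
        exposure_name=exposure_name or table.trait_name,
        target_gene=target_gene, snp_ids=kept_ids,
        r2_threshold=r2_threshold, p_threshold=p_threshold,
        per_snp_f=f_stats, r2_explained=r2_exp, table=kept_table)


def select_instruments(table: SummaryTable, ld: LDMatrix,
                       p_threshold: float = 5e-8,
                       r2_threshold: float = 0.1,
                       region: GeneRegion | None = None,
                       exposure_name: str | None = None) -> InstrumentSet:
    """Full selection pipeline: [region restriction] -> significance filter -> clump."""
    sub = table
    gene = "genome-wide"
    if region is not None:
        sub = restrict_to_region(sub, region)
        gene = region.gene
    sub = filter_significant(sub, p_threshold)
    return greedy_clump(sub, ld, r2_threshold, exposure_name=exposure_name,
                        target_gene=gene, p_threshold=p_threshold)
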