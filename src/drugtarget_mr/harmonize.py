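"""Allele harmonization of exposure and outcome summary statistics.

Both tables are assumed to report effects on the forward strand.  SNPs are
inner-joined on id; where the outcome's effect/other alleles are swapped
relative to the exposure, the outcome beta is negated (and its eaf
complemented); allele pairs that differ as sets are dropped and counted.
Palindromic variants (A/T or C/G) are retained and flagged — never
frequency-realigned — and no proxy variants are substituted for missing
outcome records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SummaryTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True when the allele pair is its own reverse complement ({A,T} or {C,G})."""
    return _COMPLEMENT.get(effect_allele.upper()) == other_allele.upper()


@dataclass
class HarmonizedSet:
    """Allele-aligned (beta_x, beta_y) vectors ready for the MR estimators."""

    snp_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    palindromic_flags: np.ndarray
    n_dropped_incompatible: int = 0
    eaf_x: np.ndarray | None = None
    ambiguous_flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y", "palindromic_flags"):
            v = np.asarray(getattr(self, name))
            if len(v) != n:
                raise ValueError(f"{name} length {len(v)} != {n} SNPs")
            setattr(self, name, v)
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def ratios(self) -> np.ndarray:
        return self.beta_y / self.beta_x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids, "beta_x": self.beta_x, "se_x": self.se_x,
            "beta_y": self.beta_y, "se_y": self.se_y,
            "palindromic": self.palindromic_flags.astype(bool),
        })

    def drop(self, snp_ids) -> "HarmonizedSet":
        """New set without the listed SNPs."""
        to_drop = set(snp_ids)
        unknown = to_drop - set(self.snp_ids)
        if unknown:
            raise KeyError(f"SNPs not in harmonized set: {sorted(unknown)}")
        keep = np.array([s not in to_drop for s in self.snp_ids])
        if keep.sum() < 1:
            raise ValueError("cannot drop every instrument")
        return HarmonizedSet(
            [s for s, k in zip(self.snp_ids, keep) if k],
            self.beta_x[keep], self.se_x[keep],
            self.beta_y[keep], self.se_y[keep],
            self.palindromic_flags[keep], self.n_dropped_incompatible,
            None if self.eaf_x is None else self.eaf_x[keep])


def harmonize(exposure: SummaryTable, outcome: SummaryTable,
              flag_ambiguous_eaf: float | None = None) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele convention.

    ``flag_ambiguous_eaf``, if given (e.g. 0.08), additionally flags
    palindromic SNPs with |eaf - 0.5| below it as strand-ambiguous — for
    reporting only, nothing is dropped or realigned.
    """
    ex = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")
    shared = [s for s in exposure.df["snp_id"] if s in out.index]
    if not shared:
        raise ValueError("no shared variants between exposure and outcome")

    ids, bx, sx, by, sy, pal, eafx = [], [], [], [], [], [], []
    dropped = 0
    for s in shared:
        e, o = ex.loc[s], out.loc[s]
        ea, oa = e["effect_allele"], e["other_allele"]
        if (o["effect_allele"], o["other_allele"]) == (ea, oa):
            beta_y = o["beta"]
        elif (o["effect_allele"], o["other_allele"]) == (oa, ea):
            beta_y = -o["beta"]
        else:
            dropped += 1
            continue
        ids.append(s)
        bx.append(e["beta"]); sx.append(e["se"])
        by.append(beta_y); sy.append(o["se"])
        pal.append(is_palindromic(ea, oa))
        eafx.append(e["eaf"])

    h = HarmonizedSet(ids, np.array(bx), np.array(sx), np.array(by),
                      np.array(sy), np.array(pal, dtype=bool),
                      n_dropped_incompatible=dropped,
                      eaf_x=np.array(eafx, dtype=float))
    if flag_ambiguous_eaf is not None:
        with np.errstate(invalid="ignore"):
            h.ambiguous_flags = (h.palindromic_flags
                                 & (np.abs(h.eaf_x - 0.5) < flag_ambiguous_eaf))
    return h


def orient_positive(h: HarmonizedSet) -> HarmonizedSet:
    """Flip each SNP so beta_x > 0 (joint sign flip of beta_x, beta_y); idempotent.

    Wald ratios beta_y/beta_x are unchanged.  A zero exposure effect has no
    defined orientation and is an error.
    """
    if np.any(h.beta_x == 0):
        zero = [s for s, b in zip(h.snp_ids, h.beta_x) if b == 0]
        raise ValueError(f"beta_x is exactly 0 for {zero}; orientation undefined")
    sign = np.sign(h.beta_x)
    return HarmonizedSet(list(h.snp_ids), h.beta_x * sign, h.se_x.copy(),
                         h.beta_y * sign, h.se_y.copy(),
                         h.palindromic_flags.copy(),
                         h.n_dropped_incompatible,
                         None if h.eaf_x is None else h.eaf_x.copy())
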