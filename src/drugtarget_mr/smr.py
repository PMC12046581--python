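"""Summary-based MR (SMR) and the HEIDI linkage-vs-causality test.

SMR estimates the effect of gene expression on an outcome from the top
cis-eQTL: with z1 = b_gwas/se_gwas and z2 = b_eqtl/se_eqtl,

    T_SMR = z1^2 z2^2 / (z1^2 + z2^2),  p from chi-square(1),
    b_SMR = b_gwas / b_eqtl  (outcome units per +1 expression unit).

HEIDI asks whether the ratio b_gwas/b_eqtl is constant across cis SNPs in
moderate LD with the top eQTL — as it must be when one shared causal
variant drives both traits — or heterogeneous, as under linkage of two
distinct causal variants.  Per-SNP deviations d_i = b_SMR(i) - b_SMR(top)
are combined with a first-order delta-method covariance (LD-correlated
within each trait, traits independent) into T_HEIDI = sum z_d^2, whose
null is a weighted chi-square mixture over the eigenvalues of corr(z_d),
evaluated here by seeded Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import harmonize
from .instruments import restrict_to_region
from .io import GeneRegion, LDMatrix, SummaryTable

log = logging.getLogger(__name__)

#: reference-tool default eQTL p ceiling for HEIDI SNP eligibility
HEIDI_P_EQTL_MAX = 1.57e-3


@dataclass
class CisDataset:
    """eQTL and outcome-GWAS summary statistics over one cis region.

    Both tables are restricted to ``region`` (gene plus flank, default
    1 Mb) at construction; every retained SNP must appear in ``ld``.
    """

    gene: str
    tissue: str
    eqtl: SummaryTable
    gwas: SummaryTable
    ld: LDMatrix
    region: GeneRegion

    def __post_init__(self) -> None:
        self.eqtl = restrict_to_region(self.eqtl, self.region)
        self.gwas = restrict_to_region(self.gwas, self.region)
        for t in (self.eqtl, self.gwas):
            for s in t.df["snp_id"]:
                self.ld.index_of(s)


@dataclass
class SMRResult:
    gene: str
    tissue: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0


def select_top_eqtl(data: CisDataset, p_threshold: float = 5e-8,
                    maf_min: float = 0.01) -> pd.Series:
    """Top cis-eQTL: smallest eQTL p among SNPs passing the significance and
    MAF filters; ties broken by larger |z|, then snp_id.  Raises if no SNP
    qualifies (the gene is skipped, as genes without instruments are)."""
    df = data.eqtl.df
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    ok = (df["pval"] < p_threshold) & maf.notna() & (maf > maf_min)
    cand = df.loc[ok].copy()
    if cand.empty:
        raise ValueError(
            f"{data.gene}/{data.tissue}: no significant cis-eQTL "
            f"(p < {p_threshold:g}, MAF > {maf_min:g})")
    cand["absz"] = (cand["beta"] / cand["se"]).abs()
    cand = cand.sort_values(["pval", "absz", "snp_id"],
                            ascending=[True, False, True], kind="mergesort")
    return cand.iloc[0].drop("absz")


def smr_test(b_gwas: float, se_gwas: float, b_eqtl: float, se_eqtl: float
             ) -> tuple[float, float, float]:
    """SMR statistic at one SNP; returns (b_smr, se_smr, p_smr)."""
    if b_eqtl == 0:
        raise ValueError("b_eqtl must be nonzero")
    if se_gwas <= 0 or se_eqtl <= 0:
        raise ValueError("standard errors must be positive")
    z1 = b_gwas / se_gwas
    z2 = b_eqtl / se_eqtl
    t_smr = (z1 ** 2 * z2 ** 2) / (z1 ** 2 + z2 ** 2)
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    b_smr = b_gwas / b_eqtl
    se_smr = abs(b_smr) / np.sqrt(t_smr) if t_smr > 0 else np.inf
    return float(b_smr), float(se_smr), p_smr


def positive_control_filter(genes: list[str], smr_vs_sbp_p: dict,
                            alpha: float = 0.05) -> list[str]:
    """Keep genes whose expression is associated with the positive-control
    trait (p < alpha) in at least one tissue; values may be scalars or
    per-tissue iterables of p-values."""
    kept = []
    for g in genes:
        p = smr_vs_sbp_p.get(g)
        if p is None:
            continue
        ps = [p] if np.isscalar(p) else list(p)
        if any(v < alpha for v in ps):
            kept.append(g)
    return kept


def heidi_select_snps(data: CisDataset, top_snp: str,
                      r2_low: float = 0.05, r2_high: float = 0.9,
                      p_eqtl_max: float = HEIDI_P_EQTL_MAX,
                      maf_min: float = 0.01,
                      m_max: int = 20) -> list[str]:
    """cis SNPs usable for HEIDI: in moderate LD with the top eQTL
    (r2_low <= r^2 <= r2_high, avoiding collinearity at both extremes),
    eQTL p < p_eqtl_max, MAF > maf_min; capped at the m_max smallest eQTL p."""
    df = data.eqtl.df
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    rows = []
    for idx, row in df.iterrows():
        s = row["snp_id"]
        if s == top_snp:
            continue
        r2 = data.ld.r2_between(s, top_snp)
        if not (r2_low <= r2 <= r2_high):
            continue
        if not (row["pval"] < p_eqtl_max):
            continue
        if pd.isna(maf[idx]) or maf[idx] <= maf_min:
            continue
        rows.append((s, row["pval"]))
    if len(rows) > m_max:
        rows = sorted(rows, key=lambda t: (t[1], t[0]))[:m_max]
        order = {s: i for i, s in enumerate(df["snp_id"])}
        rows = sorted(rows, key=lambda t: order[t[0]])
    return [s for s, _ in rows]


def _aligned_arrays(data: CisDataset, snp_ids: list[str]):
    """Allele-aligned (b_eqtl, se_eqtl, b_gwas, se_gwas) for the given SNPs."""
    h = harmonize(data.eqtl.subset(snp_ids), data.gwas)
    idx = {s: i for i, s in enumerate(h.snp_ids)}
    missing = [s for s in snp_ids if s not in idx]
    if missing:
        raise KeyError(f"SNPs missing from harmonized cis data: {missing}")
    order = [idx[s] for s in snp_ids]
    return (h.beta_x[order], h.se_x[order], h.beta_y[order], h.se_y[order])


def mixture_chi2_tail(lam: np.ndarray, t: float, mc_draws: int = 100_000,
                      seed: int | None = 0) -> float:
    """P(sum_k lam_k chi2_1k >= t) by seeded Monte Carlo.

    With lam all 1 this is the chi-square(len(lam)) upper tail; the +1/(N+1)
    correction keeps the estimate strictly inside (0, 1].
    """
    lam = np.clip(np.asarray(lam, dtype=float), 0.0, None)
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((mc_draws, len(lam)))
    t_sim = (g ** 2) @ lam
    return float((np.count_nonzero(t_sim >= t) + 1) / (mc_draws + 1))


def heidi_test(data: CisDataset, top_snp: str, snps: list[str],
               mc_draws: int = 100_000, seed: int | None = 0,
               ridge: float = 1e-8) -> tuple[float | None, int]:
    """HEIDI heterogeneity test; returns (p_heidi, n_heidi_snps).

    With fewer than 3 eligible SNPs the test is underpowered and p_heidi is
    returned as None (logged).  The null tail of T_HEIDI is a mixture
    sum_k lambda_k chi2_1 over the eigenvalues of corr(z_d), evaluated by
    seeded Monte Carlo with ``mc_draws`` samples.
    """
    m = len(snps)
    if m < 1:
        log.info("HEIDI skipped for %s: no eligible SNPs", top_snp)
        return None, 0
    if m < 3:
        log.info("HEIDI p withheld for %s: only %d eligible SNPs (<3)",
                 top_snp, m)
        return None, m

    all_ids = [top_snp] + list(snps)
    be, se_e, bg, se_g = _aligned_arrays(data, all_ids)
    if np.any(be == 0):
        raise ValueError("zero eQTL effect among HEIDI SNPs")
    r = data.ld.submatrix(all_ids).r

    # d_i = bg_i/be_i - bg_0/be_0 ; delta-method covariance over the joint
    # normal (b_gwas, b_eqtl) at all SNPs, traits independent.
    grad_g = np.zeros((m, m + 1))
    grad_e = np.zeros((m, m + 1))
    grad_g[:, 0] = -1.0 / be[0]
    grad_e[:, 0] = bg[0] / be[0] ** 2
    for i in range(m):
        grad_g[i, i + 1] = 1.0 / be[i + 1]
        grad_e[i, i + 1] = -bg[i + 1] / be[i + 1] ** 2
    cov_g = r * np.outer(se_g, se_g)
    cov_e = r * np.outer(se_e, se_e)
    cov_d = grad_g @ cov_g @ grad_g.T + grad_e @ cov_e @ grad_e.T

    var_d = np.diag(cov_d).copy()
    if np.any(var_d <= 0) or not np.all(np.isfinite(cov_d)):
        log.warning("HEIDI covariance singular; ridge %.0e added", ridge)
        cov_d = cov_d + ridge * np.eye(m)
        var_d = np.diag(cov_d).copy()

    d = bg[1:] / be[1:] - bg[0] / be[0]
    z_d = d / np.sqrt(var_d)
    t_heidi = float(np.sum(z_d ** 2))

    corr = cov_d / np.sqrt(np.outer(var_d, var_d))
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-6:
        log.warning("HEIDI correlation not PSD (min eig %.2e); ridge added",
                    lam.min())
        corr = corr + ridge * np.eye(m)
        lam = np.linalg.eigvalsh(corr)
    p = mixture_chi2_tail(lam, t_heidi, mc_draws=mc_draws, seed=seed)
    return p, m


def run_smr(data: CisDataset, p_eqtl_threshold: float = 5e-8,
            maf_min: float = 0.01, heidi: bool = True,
            heidi_p_eqtl_max: float = HEIDI_P_EQTL_MAX,
            heidi_m_max: int = 20, mc_draws: int = 100_000,
            seed: int | None = 0) -> SMRResult:
    """Full SMR + HEIDI for one gene/tissue/outcome cell."""
    top = select_top_eqtl(data, p_eqtl_threshold, maf_min)
    top_snp = top["snp_id"]
    (be,), (se_e,), (bg,), (se_g,) = _aligned_arrays(data, [top_snp])
    b_smr, se_smr, p_smr = smr_test(bg, se_g, be, se_e)
    p_heidi, n_heidi = None, 0
    if heidi:
        snps = heidi_select_snps(data, top_snp, p_eqtl_max=heidi_p_eqtl_max,
                                 maf_min=maf_min, m_max=heidi_m_max)
        p_heidi, n_heidi = heidi_test(data, top_snp, snps,
                                      mc_draws=mc_draws, seed=seed)
    return SMRResult(gene=data.gene, tissue=data.tissue, top_snp=top_snp,
                     b_smr=b_smr, se_smr=se_smr, p_smr=p_smr,
                     p_heidi=p_heidi, n_heidi_snps=n_heidi)
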