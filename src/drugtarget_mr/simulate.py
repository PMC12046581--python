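"""Synthetic LD-structured GWAS/eQTL summary statistics with known ground truth.

Summary statistics are drawn directly from the multivariate-normal summary
model the two-sample estimators assume: given true per-SNP effects
``beta`` and an LD correlation matrix ``R``, the marginal (tagged) effects
are ``lam = R @ beta`` and the observed estimates are

    beta_hat ~ MVN(lam, S R S),   S = diag(se_j),
    se_j = sigma_trait / sqrt(2 * n * f_j * (1 - f_j)),

with exposure and outcome noise independent (two-sample design).  This is
much faster than individual-level genotype simulation and is exactly the
sampling model under which IVW, MR-Egger, SMR, HEIDI and coloc are derived.

True causal exposure effects are drawn as half-normal magnitudes, i.e. the
effect allele is oriented to raise the exposure.  Directional pleiotropy
(``alpha`` with nonzero mean, drawn independently of ``beta_x`` so InSIDE
holds) is therefore directional *relative to the exposure-raising allele*,
the regime in which MR-Egger's intercept test has power while IVW is biased.

Default sample sizes mirror the consortium-scale inputs the pipeline is
designed for (an SBP GWAS of ~7.6e5 and outcome GWAS of ~1e6); ``sigma_exposure``
defaults to 19 mmHg (the population SD of SBP) and ``sigma_outcome`` to 2.5,
the effective log-odds residual scale of a GWAS with a ~20% case fraction
(1/sqrt(phi*(1-phi))).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import LDMatrix, SummaryTable, SUMMARY_COLUMNS


# ---------------------------------------------------------------------------
# LD models

def make_ld(m_snps: int, ld_model="independent") -> LDMatrix:
    """Build an LD correlation matrix over ``m_snps`` synthetic SNPs.

    ``ld_model`` is ``"independent"``, ``("ar1", rho)`` with
    r(i,j) = rho**|i-j|, or ``("block", sizes, rho)`` giving constant
    within-block correlation ``rho`` and zero across blocks.
    """
    snp_ids = [f"rs{i + 1}" for i in range(m_snps)]
    if ld_model == "independent" or ld_model == ("independent",):
        r = np.eye(m_snps)
    elif isinstance(ld_model, tuple) and ld_model[0] == "ar1":
        rho = float(ld_model[1])
        if not -1 < rho < 1:
            raise ValueError("ar1 rho must be in (-1, 1)")
        idx = np.arange(m_snps)
        r = rho ** np.abs(idx[:, None] - idx[None, :])
    elif isinstance(ld_model, tuple) and ld_model[0] == "block":
        sizes, rho = list(ld_model[1]), float(ld_model[2])
        if sum(sizes) != m_snps:
            raise ValueError(f"block sizes sum to {sum(sizes)}, expected {m_snps}")
        if not -1 < rho < 1:
            raise ValueError("block rho must be in (-1, 1)")
        r = np.zeros((m_snps, m_snps))
        start = 0
        for s in sizes:
            r[start:start + s, start:start + s] = rho
            start += s
        np.fill_diagonal(r, 1.0)
    else:
        raise ValueError(f"unknown ld_model {ld_model!r}")
    # ar1 and equicorrelated blocks with |rho|<1 are positive definite by
    # construction; verify so downstream Cholesky cannot fail silently.
    if np.linalg.eigvalsh(r).min() < -1e-10:
        raise RuntimeError("constructed LD matrix is not PSD")
    return LDMatrix(snp_ids, r)


@dataclass
class Pleiotropy:
    """Direct SNP->outcome effects bypassing the exposure.

    ``kind`` is "none", "balanced" (mean-zero) or "directional" (mean
    ``mu_alpha``); draws are independent of the exposure effects, so the
    InSIDE condition of MR-Egger holds.
    """

    kind: str = "none"
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be >= 0")


@dataclass
class SimulationConfig:
    """Study conditions for a two-sample MR simulation.

    ``theta`` is the causal effect of the exposure on the outcome in
    log-odds per +1 exposure unit (per +1 mmHg for an SBP exposure);
    ``causal_effect_sd`` is the scale (exposure units per allele) of the
    half-normal true effect magnitudes at causal SNPs.
    """

    m_snps: int = 50
    ld_model: object = "independent"
    n_exposure: int = 757_601
    n_outcome: int = 1_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    k_causal: int | None = None  # None: every SNP is causal
    causal_effect_sd: float = 0.5
    theta: float = 0.02
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    sigma_exposure: float = 19.0
    sigma_outcome: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        if self.k_causal is None:
            self.k_causal = self.m_snps
        if not (0 <= self.k_causal <= self.m_snps):
            raise ValueError("k_causal must be in [0, m_snps]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if isinstance(self.pleiotropy, dict):
            self.pleiotropy = Pleiotropy(**self.pleiotropy)
        if isinstance(self.ld_model, list):
            self.ld_model = tuple(
                tuple(x) if isinstance(x, list) else x for x in self.ld_model)


@dataclass
class TruthRecord:
    """Ground truth underlying one simulated dataset."""

    causal_snp_indices: np.ndarray
    true_beta_x: np.ndarray
    true_alpha: np.ndarray
    theta: float
    ld_used: LDMatrix

    def to_json(self) -> str:
        return json.dumps({
            "causal_snp_indices": self.causal_snp_indices.tolist(),
            "true_beta_x": self.true_beta_x.tolist(),
            "true_alpha": self.true_alpha.tolist(),
            "theta": self.theta,
        })


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def _make_table(trait_name: str, trait_type: str, trait_units: str,
                snp_ids: list[str], pos: np.ndarray, eaf: np.ndarray,
                beta: np.ndarray, se: np.ndarray, n: int,
                n_cases: float = np.nan, chrom: str = "1") -> SummaryTable:
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos.astype(int),
        "effect_allele": "A", "other_allele": "G",
        "eaf": eaf, "beta": beta, "se": se,
        "pval": _two_sided_p(beta, se),
        "n": float(n), "n_cases": n_cases,
    }, columns=SUMMARY_COLUMNS)
    return SummaryTable(trait_name, trait_type, df, trait_units)


def _marginal_se(sigma: float, n: int, f: np.ndarray) -> np.ndarray:
    return sigma / np.sqrt(2.0 * n * f * (1.0 - f))


def _draw(rng: np.random.Generator, lam: np.ndarray, se: np.ndarray,
          chol_r: np.ndarray) -> np.ndarray:
    z = rng.standard_normal(len(lam))
    return lam + se * (chol_r @ z)


def _chol(r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        # PSD but singular (e.g. perfect LD): eigendecomposition fallback
        w, v = np.linalg.eigh(r)
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_two_sample(config: SimulationConfig
                        ) -> tuple[SummaryTable, SummaryTable, TruthRecord]:
    """Simulate exposure (quantitative, mmHg) and outcome (binary, log-odds)
    summary statistics under ``config``; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    ld = make_ld(m, config.ld_model)
    f = rng.uniform(*config.maf_range, size=m)
    causal = np.sort(rng.choice(m, size=config.k_causal, replace=False))

    beta_x = np.zeros(m)
    beta_x[causal] = np.abs(rng.normal(0.0, config.causal_effect_sd,
                                       size=config.k_causal))
    alpha = np.zeros(m)
    pl = config.pleiotropy
    if pl.kind == "balanced":
        alpha[causal] = rng.normal(0.0, pl.sigma_alpha, size=config.k_causal)
    elif pl.kind == "directional":
        alpha[causal] = rng.normal(pl.mu_alpha, pl.sigma_alpha,
                                   size=config.k_causal)

    lam_x = ld.r @ beta_x
    lam_y = config.theta * lam_x + ld.r @ alpha
    se_x = _marginal_se(config.sigma_exposure, config.n_exposure, f)
    se_y = _marginal_se(config.sigma_outcome, config.n_outcome, f)

    chol_r = _chol(ld.r)
    bx_hat = _draw(rng, lam_x, se_x, chol_r)
    by_hat = _draw(rng, lam_y, se_y, chol_r)

    pos = (np.arange(m) + 1) * 10_000
    exposure = _make_table("SBP", "quantitative", "mmHg", ld.snp_ids, pos, f,
                           bx_hat, se_x, config.n_exposure)
    outcome = _make_table("outcome", "binary", "log-odds", ld.snp_ids, pos, f,
                          by_hat, se_y, config.n_outcome,
                          n_cases=round(0.2 * config.n_outcome))
    truth = TruthRecord(causal, beta_x, alpha, config.theta, ld)
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# cis-region eQTL/GWAS pairs for SMR, HEIDI and colocalization

def simulate_eqtl_gwas_pair(m_snps: int = 100,
                            scenario="shared_causal",
                            b_eqtl: float = 0.8,
                            b_gwas: float = 0.15,
                            n_eqtl: int = 600,
                            n_gwas: int = 500_000,
                            ld_model=("ar1", 0.9),
                            maf_range: tuple[float, float] = (0.1, 0.5),
                            sigma_eqtl: float = 1.0,
                            sigma_gwas: float = 2.5,
                            r_tol: float = 0.05,
                            seed: int = 0,
                            ) -> tuple[SummaryTable, SummaryTable, TruthRecord, LDMatrix]:
    """Simulate a cis region observed in an eQTL study and in a GWAS.

    Scenarios: ``"shared_causal"`` (one central SNP drives both traits, the
    HEIDI null and coloc H4), ``("linked_causal", r_between)`` (two distinct
    causal SNPs in LD r ~= r_between, the linkage alternative / coloc H3) and
    ``"null"`` (no effects, coloc H0).  Effect sizes default to a strong top
    cis-eQTL (0.8 expression SD per allele at n~600, the GTEx tissue scale)
    and a strong GWAS signal.
    """
    rng = np.random.default_rng(seed)
    ld = make_ld(m_snps, ld_model)
    f = rng.uniform(*maf_range, size=m_snps)

    beta_e = np.zeros(m_snps)
    beta_g = np.zeros(m_snps)
    centre = m_snps // 2
    if scenario == "shared_causal":
        causal = np.array([centre])
        beta_e[centre] = b_eqtl
        beta_g[centre] = b_gwas
    elif isinstance(scenario, tuple) and scenario[0] == "linked_causal":
        r_between = float(scenario[1])
        diff = np.abs(np.abs(ld.r) - r_between)
        np.fill_diagonal(diff, np.inf)
        i, j = np.unravel_index(np.argmin(diff), diff.shape)
        if diff[i, j] > r_tol:
            raise ValueError(
                f"no SNP pair with |r| within {r_tol} of {r_between} "
                f"under this LD model (closest {ld.r[i, j]:.3f})")
        i, j = sorted((i, j))
        causal = np.array([i, j])
        beta_e[i] = b_eqtl
        beta_g[j] = b_gwas
    elif scenario == "null":
        causal = np.array([], dtype=int)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    lam_e = ld.r @ beta_e
    lam_g = ld.r @ beta_g
    se_e = _marginal_se(sigma_eqtl, n_eqtl, f)
    se_g = _marginal_se(sigma_gwas, n_gwas, f)
    chol_r = _chol(ld.r)
    be_hat = _draw(rng, lam_e, se_e, chol_r)
    bg_hat = _draw(rng, lam_g, se_g, chol_r)

    # positions span ~1 Mb so a gene at the centre with a 1 Mb flank holds all
    pos = (np.arange(m_snps) + 1) * max(1, 1_000_000 // (m_snps + 1))
    eqtl = _make_table("expression", "quantitative", "expression SD",
                       ld.snp_ids, pos, f, be_hat, se_e, n_eqtl)
    gwas = _make_table("outcome", "binary", "log-odds", ld.snp_ids, pos, f,
                       bg_hat, se_g, n_gwas, n_cases=round(0.2 * n_gwas))
    truth = TruthRecord(causal, beta_e, beta_g, float("nan"), ld)
    return eqtl, gwas, truth, ld


def write_simulation(prefix: str | Path, exposure: SummaryTable,
                     outcome: SummaryTable, truth: TruthRecord) -> None:
    """Write exposure.tsv / outcome.tsv / ld.tsv / truth.json under a prefix."""
    from .io import write_ld_matrix, write_summary_table
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    write_summary_table(exposure, prefix / "exposure.tsv")
    write_summary_table(outcome, prefix / "outcome.tsv")
    write_ld_matrix(truth.ld_used, prefix / "ld.tsv")
    (prefix / "truth.json").write_text(truth.to_json() + "\n")
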