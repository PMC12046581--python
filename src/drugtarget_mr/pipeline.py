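"""Study orchestration: instruments -> harmonize -> MR (+ sensitivity
estimators) -> scaled ORs -> Bonferroni calls -> drug-vs-reference
difference tests -> SMR/HEIDI -> colocalization, from one config.

The design mirrors a two-stage drug-target MR study: (i) two-sample MR of
a genome-wide exposure instrument set (clumped at r^2 < 0.001) and of
per-drug-target cis instrument sets (gene +/- 100 kb, r^2 < 0.1) against a
panel of binary outcomes plus negative-control outcomes; (ii) SMR + HEIDI
per gene/tissue/outcome with colocalization for nominally significant
cells.  Every cell is isolated: a failure is recorded in the error table
and the remaining cells still run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import (PRIOR_SD_BINARY, PRIOR_SD_QUANTITATIVE, coloc_from_tables)
from .harmonize import HarmonizedSet, harmonize
from .instruments import InstrumentSet, select_instruments
from .io import (GeneRegion, LDMatrix, SummaryTable, read_gene_regions,
                 read_ld_matrix, read_summary_table)
from .mr import (MRResult, bonferroni_classify, difference_test, ivw,
                 mr_egger, simple_median, weighted_median)
from .smr import CisDataset, run_smr

log = logging.getLogger(__name__)


@dataclass
class DrugTarget:
    name: str
    gene: str
    r2_threshold: float = 0.1


@dataclass
class EqtlDataset:
    gene: str
    tissue: str
    file: str
    ld: str
    gwas_files: dict[str, str] | None = None  # outcome name -> cis GWAS file; None = use outcome files
    sbp_file: str | None = None  # cis SBP stats for the positive-control screen


@dataclass
class StudyConfig:
    """Inputs and thresholds of one study run (all paths relative to ``base_dir``)."""

    exposure_file: str
    ld_file: str
    outcomes: dict[str, str]
    gene_regions_file: str | None = None
    drug_targets: list[DrugTarget] = field(default_factory=list)
    negative_controls: dict[str, str] = field(default_factory=dict)
    eqtl: list[EqtlDataset] = field(default_factory=list)
    exposure_name: str = "SBP"
    p_threshold: float = 5e-8
    genome_wide_r2: float = 0.001
    flank_bp: int = 100_000
    eqtl_flank_bp: int = 1_000_000
    scale_factor: float = -10.0
    n_tests_mr: int = 35
    n_tests_smr: int = 147
    n_boot: int = 5000
    mc_draws: int = 100_000
    coloc_trigger_p: float = 0.05
    seed: int = 0
    base_dir: str = "."

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1 and 0 < self.genome_wide_r2 < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.scale_factor == 0:
            raise ValueError("scale_factor must be nonzero")
        self.drug_targets = [DrugTarget(**t) if isinstance(t, dict) else t
                             for t in self.drug_targets]
        self.eqtl = [EqtlDataset(**e) if isinstance(e, dict) else e
                     for e in self.eqtl]

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        cfg = json.loads(path.read_text())
        cfg.setdefault("base_dir", str(path.parent))
        return cls(**cfg)

    def path(self, rel: str) -> Path:
        return Path(self.base_dir) / rel


@dataclass
class StudyResult:
    mr_report: pd.DataFrame
    diff_report: pd.DataFrame
    smr_report: pd.DataFrame
    coloc_report: pd.DataFrame
    errors: pd.DataFrame
    manifest: dict
    instruments: dict[str, InstrumentSet] = field(default_factory=dict)
    harmonized: dict[tuple[str, str], HarmonizedSet] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("mr_report", self.mr_report),
                         ("diff_report", self.diff_report),
                         ("smr_report", self.smr_report),
                         ("coloc_report", self.coloc_report),
                         ("errors", self.errors)):
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g", na_rep="NA")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def _mr_row(exposure: str, outcome: str, res: MRResult, n_tests: int,
            negative_control: bool, note: str = "") -> dict:
    call = bonferroni_classify(res.pval, n_tests)
    return {
        "exposure": exposure, "outcome": outcome, "method": res.method,
        "n_snps": res.n_snps, "beta": res.beta, "se": res.se,
        "ci_low": res.ci_low, "ci_high": res.ci_high, "pval": res.pval,
        "or_scaled": res.or_scaled, "or_ci_low": res.or_ci_low,
        "or_ci_high": res.or_ci_high, "q_stat": res.q_stat,
        "egger_intercept": res.egger_intercept,
        "egger_intercept_p": res.egger_intercept_p,
        "significance": call.category, "threshold": call.threshold,
        "negative_control": negative_control, "note": note,
    }


def effect_effect_table(h: HarmonizedSet, mr: MRResult) -> pd.DataFrame:
    """Plot-ready per-SNP effect-effect table (no rendering)."""
    df = h.to_frame()
    df["ratio"] = df["beta_y"] / df["beta_x"]
    df["slope"] = mr.beta
    df["intercept"] = mr.egger_intercept if mr.egger_intercept is not None else 0.0
    return df


def _analyze_cell(exposure_name: str, inst: InstrumentSet,
                  outcome_name: str, outcome: SummaryTable,
                  cfg: StudyConfig, negative_control: bool,
                  note: str = "") -> tuple[list[dict], MRResult, HarmonizedSet]:
    h = harmonize(inst.table, outcome)
    primary = ivw(h, scale_factor=cfg.scale_factor)
    rows = [_mr_row(exposure_name, outcome_name, primary, cfg.n_tests_mr,
                    negative_control, note)]
    if h.n_snps >= 3:
        for fn, kw in ((simple_median, {"n_boot": cfg.n_boot, "seed": cfg.seed}),
                       (weighted_median, {"n_boot": cfg.n_boot, "seed": cfg.seed}),
                       (mr_egger, {})):
            res = fn(h, scale_factor=cfg.scale_factor, **kw)
            rows.append(_mr_row(exposure_name, outcome_name, res,
                                cfg.n_tests_mr, negative_control, note))
    return rows, primary, h


def run_study(config: StudyConfig,
              exclude_snps: dict[str, list[str]] | None = None,
              out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full study; deterministic given the config and its seed.

    ``exclude_snps`` maps an exposure name to instrument SNPs to drop before
    estimation (leave-one-out style sensitivity reruns); the affected rows
    are flagged in the report's ``note`` column.
    """
    exclude_snps = exclude_snps or {}
    errors: list[dict] = []
    mr_rows: list[dict] = []
    diff_rows: list[dict] = []
    smr_rows: list[dict] = []
    coloc_rows: list[dict] = []
    instruments: dict[str, InstrumentSet] = {}
    harmonized: dict[tuple[str, str], HarmonizedSet] = {}

    exposure = read_summary_table(config.path(config.exposure_file),
                                  config.exposure_name, "quantitative", "mmHg")
    ld = read_ld_matrix(config.path(config.ld_file))
    regions = (read_gene_regions(config.path(config.gene_regions_file),
                                 flank_bp=config.flank_bp)
               if config.gene_regions_file else {})

    # ----- instrument selection per exposure ------------------------------
    exposures: list[tuple[str, InstrumentSet]] = []
    try:
        gw = select_instruments(exposure, ld, config.p_threshold,
                                config.genome_wide_r2,
                                exposure_name=config.exposure_name)
        exposures.append((config.exposure_name, gw))
    except Exception as exc:  # noqa: BLE001 - cell isolation by design
        errors.append({"stage": "instruments", "cell": config.exposure_name,
                       "error": str(exc)})
    for target in config.drug_targets:
        try:
            region = regions[target.gene]
            inst = select_instruments(exposure, ld, config.p_threshold,
                                      target.r2_threshold, region=region,
                                      exposure_name=target.name)
            exposures.append((target.name, inst))
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": "instruments", "cell": target.name,
                           "error": str(exc)})

    # apply requested exclusions
    pruned = []
    for name, inst in exposures:
        note = ""
        drop = exclude_snps.get(name)
        if drop:
            missing = set(drop) - set(inst.snp_ids)
            if missing:
                errors.append({"stage": "exclude", "cell": name,
                               "error": f"not instruments: {sorted(missing)}"})
            kept = [s for s in inst.snp_ids if s not in set(drop)]
            if not kept:
                errors.append({"stage": "exclude", "cell": name,
                               "error": "exclusion removes every instrument"})
                continue
            inst = InstrumentSet(inst.exposure_name, inst.target_gene, kept,
                                 inst.r2_threshold, inst.p_threshold,
                                 table=inst.table.subset(kept))
            note = "excluded:" + ",".join(sorted(set(drop)))
        pruned.append((name, inst, note))
        instruments[name] = inst

    # ----- MR per exposure x outcome --------------------------------------
    all_outcomes = ([(n, f, False) for n, f in config.outcomes.items()]
                    + [(n, f, True) for n, f in config.negative_controls.items()])
    primary_by_cell: dict[tuple[str, str], MRResult] = {}
    for out_name, out_file, is_nc in all_outcomes:
        try:
            out_tab = read_summary_table(config.path(out_file), out_name,
                                         "binary", "log-odds")
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": "read_outcome", "cell": out_name,
                           "error": str(exc)})
            continue
        for exp_name, inst, note in pruned:
            try:
                rows, primary, h = _analyze_cell(exp_name, inst, out_name,
                                                 out_tab, config, is_nc, note)
                mr_rows.extend(rows)
                primary_by_cell[(exp_name, out_name)] = primary
                harmonized[(exp_name, out_name)] = h
            except Exception as exc:  # noqa: BLE001
                errors.append({"stage": "mr", "cell": f"{exp_name}|{out_name}",
                               "error": str(exc)})

    # ----- drug vs reference difference tests -----------------------------
    for out_name, _, is_nc in all_outcomes:
        if is_nc:
            continue
        ref = primary_by_cell.get((config.exposure_name, out_name))
        if ref is None:
            continue
        for target in config.drug_targets:
            drug = primary_by_cell.get((target.name, out_name))
            if drug is None:
                continue
            d = difference_test(drug.beta, drug.se, ref.beta, ref.se)
            diff_rows.append({
                "drug_class": target.name, "exposure": config.exposure_name,
                "outcome": out_name, "beta_diff": d.beta_diff,
                "se_diff": d.se_diff, "ci_low": d.ci_low,
                "ci_high": d.ci_high, "pval": d.pval})

    # ----- SMR / HEIDI / coloc --------------------------------------------
    for eq in config.eqtl:
        try:
            eqtl_tab = read_summary_table(config.path(eq.file),
                                          f"{eq.gene} expression",
                                          "quantitative", "expression SD")
            cis_ld = read_ld_matrix(config.path(eq.ld))
            region = regions.get(eq.gene)
            if region is None:
                df = eqtl_tab.df
                region = GeneRegion(eq.gene, str(df["chrom"].iloc[0]),
                                    int(df["pos"].min()), int(df["pos"].max()))
            region = region.with_flank(config.eqtl_flank_bp)
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": "read_eqtl",
                           "cell": f"{eq.gene}|{eq.tissue}", "error": str(exc)})
            continue

        # positive-control screen: expression -> exposure SMR, p < 0.05
        if eq.sbp_file is not None:
            try:
                sbp_tab = read_summary_table(config.path(eq.sbp_file),
                                             config.exposure_name,
                                             "quantitative", "mmHg")
                data = CisDataset(eq.gene, eq.tissue, eqtl_tab, sbp_tab,
                                  cis_ld, region)
                pc = run_smr(data, config.p_threshold, heidi=False,
                             seed=config.seed)
                if not pc.p_smr < 0.05:
                    smr_rows.append({
                        "gene": eq.gene, "tissue": eq.tissue, "outcome": "",
                        "top_snp": pc.top_snp, "b_smr": np.nan,
                        "se_smr": np.nan, "p_smr": np.nan, "p_heidi": np.nan,
                        "n_heidi_snps": 0, "significance": "",
                        "note": f"failed positive control (p={pc.p_smr:.3g})"})
                    continue
            except Exception as exc:  # noqa: BLE001
                errors.append({"stage": "positive_control",
                               "cell": f"{eq.gene}|{eq.tissue}",
                               "error": str(exc)})
                continue

        gwas_files = eq.gwas_files if eq.gwas_files is not None else config.outcomes
        for out_name, out_file in gwas_files.items():
            try:
                gwas_tab = read_summary_table(config.path(out_file), out_name,
                                              "binary", "log-odds")
                data = CisDataset(eq.gene, eq.tissue, eqtl_tab, gwas_tab,
                                  cis_ld, region)
                res = run_smr(data, config.p_threshold,
                              mc_draws=config.mc_draws, seed=config.seed)
                call = bonferroni_classify(res.p_smr, config.n_tests_smr)
                smr_rows.append({
                    "gene": res.gene, "tissue": res.tissue, "outcome": out_name,
                    "top_snp": res.top_snp, "b_smr": res.b_smr,
                    "se_smr": res.se_smr, "p_smr": res.p_smr,
                    "p_heidi": res.p_heidi, "n_heidi_snps": res.n_heidi_snps,
                    "significance": call.category, "note": ""})
                if res.p_smr < config.coloc_trigger_p:
                    cres = _coloc_cell(data)
                    coloc_rows.append({
                        "gene": eq.gene, "tissue": eq.tissue,
                        "outcome": out_name, "n_snps": cres.n_snps,
                        **{f"pp_{h.lower()}": cres.pp[h] for h in
                           ("H0", "H1", "H2", "H3", "H4")}})
            except Exception as exc:  # noqa: BLE001
                errors.append({"stage": "smr",
                               "cell": f"{eq.gene}|{eq.tissue}|{out_name}",
                               "error": str(exc)})

    manifest = {
        "package_version": __version__,
        "exposure_file": config.exposure_file,
        "ld_file": config.ld_file,
        "outcomes": config.outcomes,
        "negative_controls": config.negative_controls,
        "drug_targets": [t.name for t in config.drug_targets],
        "p_threshold": config.p_threshold,
        "genome_wide_r2": config.genome_wide_r2,
        "flank_bp": config.flank_bp,
        "n_tests_mr": config.n_tests_mr,
        "n_tests_smr": config.n_tests_smr,
        "bonferroni_mr": 0.05 / config.n_tests_mr,
        "bonferroni_smr": 0.05 / config.n_tests_smr,
        "seed": config.seed,
        "exclude_snps": exclude_snps,
    }

    mr_cols = ["exposure", "outcome", "method", "n_snps", "beta", "se",
               "ci_low", "ci_high", "pval", "or_scaled", "or_ci_low",
               "or_ci_high", "q_stat", "egger_intercept", "egger_intercept_p",
               "significance", "threshold", "negative_control", "note"]
    result = StudyResult(
        mr_report=pd.DataFrame(mr_rows, columns=mr_cols),
        diff_report=pd.DataFrame(diff_rows, columns=[
            "drug_class", "exposure", "outcome", "beta_diff", "se_diff",
            "ci_low", "ci_high", "pval"]),
        smr_report=pd.DataFrame(smr_rows, columns=[
            "gene", "tissue", "outcome", "top_snp", "b_smr", "se_smr",
            "p_smr", "p_heidi", "n_heidi_snps", "significance", "note"]),
        coloc_report=pd.DataFrame(coloc_rows, columns=[
            "gene", "tissue", "outcome", "n_snps", "pp_h0", "pp_h1", "pp_h2",
            "pp_h3", "pp_h4"]),
        errors=pd.DataFrame(errors, columns=["stage", "cell", "error"]),
        manifest=manifest, instruments=instruments, harmonized=harmonized)
    if out_dir is not None:
        result.write(out_dir)
    return result


def _coloc_cell(data: CisDataset):
    from .harmonize import harmonize as _harm
    h = _harm(data.eqtl, data.gwas)
    return coloc_from_tables(h.beta_x, h.se_x, h.beta_y, h.se_y,
                             prior_sd1=PRIOR_SD_QUANTITATIVE,
                             prior_sd2=PRIOR_SD_BINARY)


def write_demo_study(out_dir: str | Path, seed: int = 0,
                     theta_by_outcome: dict[str, float] | None = None,
                     m_snps: int = 60, n_outcome: int = 1_000_000,
                     mc_draws: int = 20_000) -> Path:
    """Write a fully synthetic study (files + config JSON) and return the
    config path.

    Two drug-target genes hold the first two blocks of ten SNPs each (on
    their own chromosomes); the rest are genome-wide background.  Outcomes
    share one exposure draw and differ only in their causal effect theta
    (log-odds per mmHg); a ``theta = 0`` outcome is included as a negative
    control.  A shared-causal cis region provides the SMR/HEIDI/coloc stage.
    """
    from .io import write_gene_regions, write_ld_matrix, write_summary_table
    from .simulate import SimulationConfig, simulate_eqtl_gwas_pair, \
        simulate_two_sample

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if theta_by_outcome is None:
        theta_by_outcome = {"CAD": 0.05, "stroke": 0.03}

    def relocate(df: pd.DataFrame) -> None:
        # first two 10-SNP blocks become cis windows of the target genes
        chrom = np.full(m_snps, "3", dtype=object)
        chrom[:10] = "1"
        chrom[10:20] = "2"
        pos = df["pos"].to_numpy().copy()
        pos[10:20] = pos[:10]
        df["chrom"] = chrom
        df["pos"] = pos

    base = dict(m_snps=m_snps, k_causal=m_snps, n_outcome=n_outcome,
                seed=seed)
    outcome_files, nc_files = {}, {}
    exposure = None
    for name, theta in {**theta_by_outcome, "negctrl": 0.0}.items():
        ex, oc, truth = simulate_two_sample(SimulationConfig(
            theta=theta, **base))
        relocate(ex.df)
        relocate(oc.df)
        if exposure is None:
            exposure = ex
            write_summary_table(ex, out / "exposure.tsv")
            write_ld_matrix(truth.ld_used, out / "ld.tsv")
        fname = f"outcome_{name}.tsv"
        write_summary_table(oc, out / fname)
        if name == "negctrl":
            nc_files[name] = fname
        else:
            outcome_files[name] = fname

    pos = exposure.df["pos"]
    write_gene_regions([
        GeneRegion("G1", "1", int(pos[:10].min()), int(pos[:10].max())),
        GeneRegion("G2", "2", int(pos[10:20].min()), int(pos[10:20].max())),
    ], out / "regions.tsv")

    eqtl, cis_gwas, _, cis_ld = simulate_eqtl_gwas_pair(
        m_snps=80, scenario="shared_causal", n_gwas=100_000, seed=seed + 1)
    eqtl.df["chrom"] = "4"
    cis_gwas.df["chrom"] = "4"
    write_summary_table(eqtl, out / "eqtl_GENE.tsv")
    write_summary_table(cis_gwas, out / "cis_gwas_CAD.tsv")
    write_ld_matrix(cis_ld, out / "cis_ld.tsv")

    config = {
        "exposure_file": "exposure.tsv",
        "ld_file": "ld.tsv",
        "outcomes": outcome_files,
        "negative_controls": nc_files,
        "gene_regions_file": "regions.tsv",
        "flank_bp": 2000,
        "drug_targets": [{"name": "T1", "gene": "G1"},
                         {"name": "T2", "gene": "G2"}],
        "eqtl": [{"gene": "GENE", "tissue": "artery", "file": "eqtl_GENE.tsv",
                  "ld": "cis_ld.tsv",
                  "gwas_files": {"CAD": "cis_gwas_CAD.tsv"},
                  "sbp_file": "cis_gwas_CAD.tsv"}],
        "n_boot": 500,
        "mc_draws": mc_draws,
        "seed": seed,
    }
    cfg_path = out / "study.json"
    cfg_path.write_text(json.dumps(config, indent=2) + "\n")
    return cfg_path


def exclude_snps_rerun(config: StudyConfig, exposure: str,
                       snp_ids_to_drop: list[str],
                       out_dir: str | Path | None = None) -> StudyResult:
    """Rerun the study with the listed SNPs removed from one exposure's
    instruments; the report flags the exclusion.  Dropping every instrument
    is an error."""
    if not snp_ids_to_drop:
        return run_study(config, out_dir=out_dir)
    probe = run_study(config)
    inst = probe.instruments.get(exposure)
    if inst is None:
        raise KeyError(f"unknown exposure {exposure!r}")
    remaining = [s for s in inst.snp_ids if s not in set(snp_ids_to_drop)]
    if not remaining:
        raise ValueError("exclusion would drop every instrument")
    return run_study(config, exclude_snps={exposure: list(snp_ids_to_drop)},
                     out_dir=out_dir)
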