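"""SMR + HEIDI on simulated cis regions: shared causal variant vs linkage.

In the shared scenario one SNP drives both gene expression and the
outcome, so the expression->outcome ratio is constant across the region
and HEIDI should NOT reject (p_HEIDI > 0.01).  In the linked scenario two
distinct causal SNPs in LD r ~ 0.4 mimic the association; the ratio is
heterogeneous and HEIDI should reject (p_HEIDI < 0.01).
"""

from drugtarget_mr import (CisDataset, GeneRegion, run_smr,
                           simulate_eqtl_gwas_pair)


def analyse(scenario, label):
    eqtl, gwas, truth, ld = simulate_eqtl_gwas_pair(
        m_snps=100, scenario=scenario, n_gwas=100_000, seed=7)
    df = eqtl.df
    region = GeneRegion("GENE", "1", int(df["pos"].min()),
                        int(df["pos"].max()))
    data = CisDataset("GENE", "artery", eqtl, gwas, ld, region)
    res = run_smr(data, mc_draws=50_000, seed=7)
    print(f"{label:>24}: top eQTL {res.top_snp}, "
          f"b_SMR = {res.b_smr:+.3f} (SE {res.se_smr:.3f}), "
          f"p_SMR = {res.p_smr:.2e}, p_HEIDI = {res.p_heidi:.3f} "
          f"({res.n_heidi_snps} SNPs)")
    return res


print("b_SMR is the outcome effect per +1 SD of expression; the true value "
      "in the shared scenario is 0.15/0.8 = 0.1875.\n")
shared = analyse("shared_causal", "shared causal variant")
linked = analyse(("linked_causal", 0.4), "linkage (r ~ 0.4)")
print("\nHEIDI keeps the shared-variant signal and flags the linkage one "
      f"at the 0.01 threshold: {shared.p_heidi:.3f} vs {linked.p_heidi:.3g}.")
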