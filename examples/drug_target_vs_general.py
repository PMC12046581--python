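"""Does a drug-target effect differ from general exposure lowering?

Builds a synthetic study in which one 'drug-target' gene region carries a
larger protective effect than the genome-wide exposure signal, estimates
both by IVW, and applies the propagation-of-error difference test (the
per-outcome beta_diff of a drug-target MR study).  A negative beta_diff
means the drug-target effect is larger (more protective per mmHg) than
expected from exposure lowering alone.
"""

import numpy as np

from drugtarget_mr import (SimulationConfig, difference_test,
                           filter_significant, harmonize, ivw,
                           simulate_two_sample)

# general exposure-lowering arm: theta = 0.02 log-odds per mmHg
ex_gen, out_gen, _ = simulate_two_sample(SimulationConfig(
    m_snps=60, n_outcome=500_000, theta=0.02, seed=1))
ivw_gen = ivw(harmonize(filter_significant(ex_gen, 5e-8), out_gen))

# drug-target arm: 8 cis SNPs whose outcome effect is stronger (theta = 0.05)
ex_drug, out_drug, _ = simulate_two_sample(SimulationConfig(
    m_snps=8, n_outcome=500_000, theta=0.05, seed=2))
ivw_drug = ivw(harmonize(filter_significant(ex_drug, 5e-8), out_drug))

d = difference_test(ivw_drug.beta, ivw_drug.se, ivw_gen.beta, ivw_gen.se)

print(f"general lowering : beta = {ivw_gen.beta:+.4f} per mmHg "
      f"(OR/10mmHg-dec {ivw_gen.or_scaled:.3f}), {ivw_gen.n_snps} SNPs")
print(f"drug target      : beta = {ivw_drug.beta:+.4f} per mmHg "
      f"(OR/10mmHg-dec {ivw_drug.or_scaled:.3f}), {ivw_drug.n_snps} SNPs")
print(f"\nbeta_diff = {d.beta_diff:+.4f} "
      f"[{d.ci_low:+.4f}, {d.ci_high:+.4f}], p = {d.pval:.2e}")
print("beta_diff > 0 with small p: the drug-target effect per mmHg exceeds "
      "the general-lowering effect (simulated 0.05 vs 0.02).")
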