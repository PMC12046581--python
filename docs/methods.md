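# Methods

This note records the models implemented, the defaults and why, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would need to know.

## Two-sample MR estimators

All estimators consume a `HarmonizedSet`: allele-aligned per-SNP exposure
effects β_Xj (mmHg per effect-allele copy) and outcome effects β_Yj
(log-odds per copy) with standard errors. Instruments are assumed
uncorrelated — they are LD-clumped upstream — and exposure and outcome
samples non-overlapping (two-sample design).

- **IVW**: weighted regression through the origin, weights 1/se_Yj².
  Model-selection rule: with more than three variants (J ≥ 4) the SE is
  multiplied by max(1, √(Q/(J−1))) (multiplicative random effects, never
  smaller than fixed effects); J ≤ 3 uses fixed effects; J = 1 is the
  Wald ratio with first-order SE |se_Y/β_X| (exposure uncertainty
  ignored, the standard two-sample approximation; both cutoffs are
  arguments). An LD-aware generalized fit is available via the `ld=`
  argument of `ivw()` but is not the default, matching the common
  practice of treating clumped instruments as independent.
- **Medians**: the simple median of Wald ratios and the 50th weighted
  percentile with weights β_Xj²/se_Yj² (inverse first-order ratio
  variance), interpolated at cumulative weight 0.5 measured at the
  centre of each SNP's mass. SEs are the SD over a parametric bootstrap
  (both β̂_X and β̂_Y resampled at their SEs; default 5 000 draws,
  seeded). Reported p-values are normal-theory on the bootstrap SE.
- **MR-Egger**: weighted least squares with intercept after orienting
  every SNP exposure-increasing (the intercept is only defined relative
  to that orientation; `orient_positive` is idempotent and leaves Wald
  ratios unchanged). Slope and intercept SEs carry the same
  multiplicative dispersion inflation max(1, √(Q/(J−2))). The intercept
  test uses the normal reference by default (`intercept_reference="t"`
  switches to t with J−2 df).
- **Scaling**: ORs are exp(factor·β) with factor −10 by default — per
  10-mmHg *decrease* — with the 95% CI multiplier fixed at 1.959964.
- **Difference test**: β_diff = β_drug − β_ref on the per-1-mmHg
  log-odds scale, SE √(se₁²+se₂²), two-sided normal p, reported
  unadjusted. The per-1-mmHg scale is used because it is the scale on
  which the IVW estimates themselves live; the per-10-mmHg OR is a
  presentation transform only.
- **Multiplicity**: 0.05/n_tests with a nominal band up to 0.05. The
  default study counts are 35 MR tests (5 exposures × 7 outcomes,
  threshold ≈ 0.0014) and 147 SMR tests (threshold ≈ 0.0003).

## Instruments

Selection is region restriction (1-based inclusive, `start − flank ≤ pos
≤ end + flank`; 100 kb flanks for drug-target genes, 1 Mb for cis-eQTLs),
then p < 5×10⁻⁸, then greedy clumping on a user-supplied LD matrix:
repeatedly retain the smallest-p SNP and discard everything at r² at or
above the threshold (0.1 for drug targets, 0.001 genome-wide). Ties on p
break on (chrom, pos, snp_id), which makes the output invariant to input
row order. There is no reference-panel lookup: LD is an explicit input,
and genome-wide use expects per-chromosome blocks with cross-block r²
treated as zero.

Instrument strength is the per-SNP F = (β/se)² (the one-parameter
approximation; the aggregate regression F over J instruments is exposed
as `aggregate_f`). Variance explained uses the z-based per-SNP form
R² = z²/(z² + n − 2), chosen because summary files do not carry the trait
variance that the 2f(1−f)β² form needs.

## Harmonization

Inner join on snp_id; swapped alleles negate the outcome beta (and
complement its frequency); allele pairs that differ as sets are dropped
and counted. All alleles are assumed forward-strand: palindromic (A/T,
C/G) variants are retained and flagged, never frequency-realigned, and no
proxy variants are substituted — missing outcome records silently drop
the SNP with a logged count. An optional `flag_ambiguous_eaf` marks
palindromic SNPs with allele frequency near 0.5 for reporting only.

## SMR and HEIDI

The top cis-eQTL is the smallest-p SNP passing p < 5×10⁻⁸ and MAF > 0.01
(ties: larger |z|, then id); genes with no qualifying eQTL are skipped,
and a positive-control screen (expression→exposure SMR p < 0.05 in at
least one tissue) gates entry to the outcome analyses. HEIDI SNPs are cis
SNPs with 0.05 ≤ r² ≤ 0.9 to the top eQTL (avoiding collinearity at both
extremes), eQTL p below 1.57×10⁻³ (the conventional tool default — the
5×10⁻⁸ threshold applies to instrument selection, not HEIDI eligibility),
capped at the 20 smallest eQTL p. Fewer than three eligible SNPs withhold
p_HEIDI (logged) rather than reporting an underpowered number.

The HEIDI statistic sums squared standardized deviations d_i =
b_SMR(i) − b_SMR(top). The covariance of d is first-order delta method
over the jointly normal (b̂_GWAS, b̂_eQTL) at all SNPs, with within-trait
correlations equal to LD r and the two traits independent. The null
distribution Σ λ_k χ²₁ over the eigenvalues of corr(z_d) is evaluated by
seeded Monte Carlo (default 10⁵ draws; the `mixture_chi2_tail` helper is
verified against the exact chi-square tail when all eigenvalues are 1).
Monte Carlo was chosen over series/saddlepoint approximations because it
is directly verifiable against that oracle; the +1/(N+1) correction keeps
p in (0, 1]. A singular covariance receives a 1e-8 ridge, logged.

## Colocalization

Wakefield log-ABFs with effect-size prior SD 0.15 for quantitative traits
and 0.2 for binary (log-odds) traits — the conventional defaults; only
the configuration priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ are fixed by the
study design. All enumeration is in log space (log-sum-exp), with H3
computed stably as log(S1·S2 − S12) via expm1; m = 1 gives exactly
PP(H3) = 0. The one-causal-variant-per-trait assumption is inherent to
the enumeration and is stated in the result object.

## Synthetic-data generator

Summary statistics are drawn from the multivariate-normal summary model
directly: marginal effects λ = Rβ (LD tagging), observed β̂ ~ MVN(λ, SRS)
with S = diag(σ_trait/√(2nf(1−f))), exposure and outcome draws
independent. This is exactly the sampling model the estimators assume —
so passing recovery/calibration tests validates the estimators, not the
model — and it is orders of magnitude faster than genotype-level
simulation. What it does **not** emulate: finite-sample LD estimation
noise, allele-frequency mismatch between studies, sample overlap,
population stratification, liability-scale case/control effects (binary
outcomes are simulated directly on the log-odds scale with
σ_outcome = 2.5, the effective residual scale of a ~20% case-fraction
GWAS), or winner's-curse from discovery/replication asymmetry. Results on
real data can therefore differ even when all tests pass.

Defaults mirror consortium-scale inputs: exposure n = 757 601 with
σ = 19 mmHg (the SBP GWAS scale), outcome n = 10⁶, MAF ~ U(0.05, 0.5),
per-allele causal effects half-normal with SD 0.5 mmHg. Drawing effect
*magnitudes* (effect allele oriented to raise the exposure) is a
deliberate convention: directional pleiotropy (α with nonzero mean, drawn
independently of β_X so InSIDE holds) is then directional relative to the
exposure-raising allele, the regime in which IVW is biased while MR-Egger
stays consistent and its intercept test has power. cis-region pairs place
one shared causal SNP (HEIDI null / coloc H4), two SNPs at LD r ≈
r_between (linkage / H3; an error if no pair within 0.05 of the request
exists under the LD model), or nothing (H0), with eQTL n = 600 and effect
0.8 expression SD — a strong top cis-eQTL at tissue-bank scale.

## Validation problem sizes

The stochastic suites use 500 replicates of 50-instrument studies at
n = 2×10⁵ per sample for IVW bias (<5% of θ = 0.02) and CI coverage
([0.93, 0.97]); 500 replicates of 100-SNP studies with directional
pleiotropy (μ_α = 0.015, σ_α = 0.004) for Egger intercept power (≥80%)
and the Egger-vs-IVW bias comparison; 200 seeds each for HEIDI null
calibration (false rejection ≤3% at 0.01) and linkage power (median
p < 0.01) with 2×10⁴ Monte-Carlo draws; and 20 seeds for the coloc
scenario medians. These sizes give Monte-Carlo standard errors well
inside the asserted margins while keeping the whole suite fast.

## Known limitations

- No MR-PRESSO, multivariable MR, Steiger filtering, proxy-SNP lookup,
  liftover, or VCF parsing; LD must be supplied, never estimated.
- The Wald-ratio SE ignores exposure-side uncertainty (second-order
  option not implemented); weak instruments therefore bias slightly
  toward the null, visible as ~1–2% attenuation in the recovery suite.
- HEIDI's delta-method covariance treats estimated eQTL effects as the
  truth in the gradients; with weak top eQTLs its calibration degrades
  (the eligibility p-threshold guards against this).
- The coloc enumeration assumes at most one causal variant per trait;
  regions with allelic heterogeneity need SuSiE-style extensions that are
  out of scope.
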