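# Methods

## Setting and model

`mrtarget` implements two-sample drug-target Mendelian randomization from
GWAS summary statistics. The exposure is a quantitative physiological trait
(blood pressure in mmHg, heart rate in bpm, or a gene-expression level) that
proxies the activity of a drug target; the outcome is a disease risk
(log-odds scale) or a quantitative phenotype (e.g. left-ventricular volume in
mL). Instruments are restricted to the cis region of the gene encoding the
target so that the causal contrast mimics pharmacological modulation of that
protein rather than of the downstream biomarker.

With harmonized per-variant marginal estimates γ̂ (exposure), Γ̂ (outcome),
outcome SEs σ_Y and signed LD correlations ρ, the fixed-effect IVW estimator
for correlated variants is the GLS solution of Γ̂ = θγ̂ + ε with
cov(ε) = Ω = diag(σ_Y)·ρ·diag(σ_Y):

- θ̂ = (γ̂ᵀΩ⁻¹γ̂)⁻¹ γ̂ᵀΩ⁻¹Γ̂, SE = (γ̂ᵀΩ⁻¹γ̂)^(-1/2);
- generalized Cochran's Q = êᵀΩ⁻¹ê with ê = Γ̂ − θ̂γ̂, df m−1;
- MR-Egger adds a free intercept (average directional pleiotropy) to the
  same GLS design, after orienting all variants to their
  exposure-increasing allele;
- leave-one-out repeats the IVW fit dropping each variant.

Assumptions: instruments are relevant (γ ≠ 0), affect the outcome only
through the exposure (no horizontal pleiotropy; Q and the Egger intercept
screen for violations, with Egger consistent under InSIDE), exposure and
outcome samples do not overlap, Ω is treated as known (no-measurement-error
convention: exposure-side noise is ignored in the weighting, appropriate for
instruments that passed a genome-wide significance screen), and all variants
at the locus target one causal parameter — the fixed-effect premise, which
is plausible precisely because the variants perturb a single gene.

Inference uses standard-normal quantiles (GLS with known covariance), not t.
Two-sided p-values and 95% CIs by default, both configurable.

## Pipeline conventions and numerical choices

- **Coordinates** are 1-based inclusive internally; only the BED reader
  converts from 0-based half-open. All inputs must share one genome build;
  builds are treated as opaque.
- **Selection**: candidates in the cis union at p ≤ 5×10⁻⁸ and MAF > 0.01
  are greedily clumped at r² < 0.1 (retain best p, prune r² ≥ threshold,
  repeat; ties on p broken by position then variant id so results are
  platform-independent). If fewer than 3 survive, both relaxations — p ≤
  1×10⁻⁴, or clumping at r² < 0.6 — are rerun and the one retaining more
  variants is adopted (tie → relaxed p), recorded in the output. Variants
  absent from the LD reference are dropped rather than assumed independent:
  an unknown correlation would corrupt Ω.
- **Harmonization**: palindromic SNPs (A/T, C/G) are excluded outright;
  SNPs with exposure-study MAF > 0.42 are excluded because both alleles sit
  too close to 50% for frequency-based strand disambiguation (the rule is
  applied to all SNPs, with a flag to restrict it to palindromic ones for
  users preferring the narrower reading). Swapped alleles negate the
  outcome beta and flip its EAF; alleles matching after complementing are
  treated as a strand difference and then matched or swapped. The
  exposure-study EAF is used for the MAF rule; the provenance log records
  this.
- **Conditioning**: if the smallest eigenvalue of ρ falls below 1e-8 (near
  duplicates under the relaxed r² < 0.6 clumping), eigenvalues are floored
  at 1e-8 before inversion and a warning is logged.
- **Wald SE** is first-order delta method σ_Y/|γ̂|, consistent with the
  estimator's weighting; a second-order option adding Γ̂²σ_X²/γ̂⁴ under the
  square root is available.
- **Degenerate inputs**: γ̂ = 0 (single instrument) and near-constant γ̂
  (Egger) are hard errors; Q and leave-one-out require m ≥ 2, Egger m ≥ 3
  and are omitted from the sensitivity report otherwise.
- **Reporting**: estimates are re-expressed per 1-unit *decrease* of the
  exposure by negation (p-value invariant), exponentiated to ORs for binary
  outcomes only, and optionally rescaled to a drug-class effect (e.g.
  9.51 mmHg) by multiplying θ̂, SE and CI bounds.
- **Pleiotropy decision rule**: a `pleiotropy_detected` flag is set when
  either the Q test or the Egger intercept is significant at α; the
  recommended report is then the Egger slope, but no silent estimator
  switching happens.
- **Mediation**: the mediator-adjusted outcome GWAS is an *input* (produced
  externally by conditional-GWAS methods such as mtCOJO). The contrast
  Δ = θ̂_primary − θ̂_adjusted is tested with SE √(SE₁² + SE₂²), which
  treats the two estimates as independent — conservative when they share
  instruments and exposure data, and flagged as such in the report. The
  attenuation verdict additionally requires |θ̂_adjusted| < |θ̂_primary|.

## The synthetic-data generator

Summary statistics are drawn directly from their asymptotic sampling
distribution rather than from individual-level genotypes: this exercises
exactly what the estimators consume, keeps runtimes at desk scale and makes
ground truth explicit.

For an m-variant locus with LD matrix R and MAFs f ~ U(0.05, 0.5): joint
(conditional) exposure effects b are drawn for the causal subset with one
shared sign per locus and magnitudes bounded away from zero
(± (0.5 + |N(0,1)|), rescaled so bᵀRb equals the locus heritability), the
marginal effects are γ = R·b, and

- γ̂ ~ MVN(γ, S_X R S_X), σ_X,ⱼ = 1/√(2fⱼ(1−fⱼ)n_exp) (unit-variance
  exposure);
- Γ̂ ~ MVN(θγ + α, S_Y R S_Y) from an independent random stream (the
  two-sample assumption), with σ_Y,ⱼ = 1/√(2fⱼ(1−fⱼ)n_out·c(1−c)) on the
  log-odds scale for a binary outcome with case fraction c, or without the
  c(1−c) factor for quantitative outcomes;
- directional pleiotropy αⱼ ~ N(α_μ, α_σ²) is planted relative to the
  exposure-increasing allele (sign(γⱼ)·αⱼ in the raw frame), which is the
  only frame in which a nonzero mean pleiotropy is a well-defined,
  InSIDE-compatible quantity — planted in the raw allele coding it would
  be averaged away by reorientation;
- a mediated fraction μ splits θ into θ_direct = (1−μ)θ plus a mediated
  remainder; the "adjusted" outcome GWAS carries θ_direct·γ + α with fresh
  noise, emulating a perfectly conditioned GWAS.

The shared effect sign and the magnitude floor reflect two features of real
drug-target analyses: variants in one gene region perturb the same protein
(the fixed-effect premise) and only variants strong enough to pass a
significance screen become instruments. Without them, LD cancellation puts
10–15% of marginal effects near zero; such variants are sign-unstable under
reorientation, which visibly attenuates the mean Egger intercept.

Alleles are drawn from non-palindromic pairs so that default simulations
survive harmonization untouched; a fixture flag plants a palindromic
variant, a MAF-0.45 variant and a swapped-allele record for harmonization
tests, and `make_fixture` writes fully deterministic toy bundles
(harmonization counts, hand-enumerable clumping, exact Egger recovery, a
planted leave-one-out outlier).

**Reference scenario** used by the test suite and `scripts/acceptance.py`:
m = 8 variants, AR(1) LD with r = 0.3, locus heritability 1%, exposure GWAS
n = 100,000, binary outcome GWAS n = 50,000 at 7% case fraction, θ = 0.05
log-odds per exposure unit. These are consortium-designs scaled to desk
runtimes (the real analyses use hundreds of thousands of samples); per-locus
power is accordingly modest, which the Monte Carlo studies absorb by
averaging over 500–2000 replicates. The heterogeneity scenario plants
per-variant effects with sd 0.05 (comparable to the causal signal,
noncentrality ≈ 20); the pleiotropy scenario uses α_μ = 0.03, α_σ = 0.01;
the mediation power scenario uses a quantitative outcome with θ = 0.5 so
that the difference z-statistic is ≈ 4.6.

## What the simulations do and do not show

Passing tests demonstrate the estimators' algebra, calibration, coverage and
diagnostic power *under the generator's assumptions*: multivariate-normal
sampling noise, a correctly specified LD matrix shared by both studies,
Hardy–Weinberg variance scaling, and no selection bias. They do not probe
winner's-curse from selecting instruments and estimating in the same sample,
LD-reference mismatch, allele-frequency differences between populations,
overlapping samples, or case-control ascertainment effects on the log-odds
approximation — all real-data hazards that the pipeline's design (two-sample
layout, reference-panel LD, exclusion rules) mitigates but these simulations
do not quantify.

## Known limitations

- The correlated-Egger fit assumes the same Ω as the IVW; with extra
  per-variant pleiotropy variance the intercept SE is optimistic (the mean
  remains unbiased).
- The mediation z-test's independence approximation is conservative; no
  product-of-coefficients decomposition is attempted.
- mtCOJO-style conditioning, LD estimation from genotypes, VCF/PLINK
  parsing and multivariable or random-effects MR are out of scope.
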