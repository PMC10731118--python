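# Methods

This note documents the statistical model behind `mrkit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Two-sample MR model and assumptions

The package estimates the causal effect θ of an exposure X on an outcome Y
from per-SNP association summary statistics measured in two non-overlapping
GWAS samples. Validity of a genetic instrument requires (1) association
with the exposure, (2) independence from confounders of X–Y, and
(3) no effect on Y except through X (exclusion restriction). Assumption (1)
is enforced by p-value selection (default 5×10⁻⁸; a suggestive 5×10⁻⁶ is
appropriate when few variants reach genome-wide significance) and audited
by the F-statistic; (2) is a design assumption; (3) is untestable per SNP
but diagnosable in aggregate, which is what the estimator battery and
MR-PRESSO are for. For a binary outcome whose GWAS effects are log odds
ratios, θ is on the log-OR-per-SD-of-exposure scale and is reported as
exp(θ) with exponentiated CI bounds.

## Harmonization

Outcome effects are re-expressed for the exposure's effect allele. Swapped
allele labels negate the outcome beta and reflect the frequency (ƒ → 1−ƒ);
strand-complement codings are complemented first (single-base alleles only
— indel strands are not guessable). Palindromic variants (A/T, C/G) carry
no strand information in their labels, so orientation is inferred from
allele frequency alone: both frequencies must fall on the same side of 0.5,
and the variant is dropped when either frequency is missing or lies in the
ambiguity window [0.42, 0.58]. The window, and the infer-by-frequency
default (a `drop_all` policy is available), follow common two-sample MR
practice; they are package decisions, configurable per call. Joining is by
variant id only — published instruments are matched across GWAS by rsID —
with positions carried along as advisory metadata.

## Instrument selection and strength

Clumping is greedy: repeatedly keep the smallest-p remaining variant (ties
broken lexicographically by id for reproducibility) and discard variants
with r² ≥ 0.001 to it on the same chromosome within 10 Mb. The r²
threshold is the field's standard for independence; the 10 Mb window is a
package default chosen to be conservative (long-range LD regions are rare
beyond that). LD comes from a local pairwise table; absent pairs count as
independent, which matches the post-clumping, mostly inter-chromosomal
instrument sets of published GWAS. Instruments missing from the outcome
GWAS can be replaced by the best local proxy with r² ≥ 0.7.

Strength: per-SNP variance explained R²_j ≈ 2β²ƒ(1−ƒ) (standardized trait),
summed over instruments, and F = (R²/k)/((1−R²)/(n−k−1)) with the exposure
GWAS sample size n. F ≤ 10 triggers a weak-instrument warning. When any
instrument lacks a frequency, R² and F are reported as unavailable rather
than imputed.

## Estimators

* **Wald ratio / IVW.** θ̂_j = β̂_Yj/β̂_Xj with first-order delta SE
  σ_Yj/|β̂_Xj| (exposure-side noise ignored — the standard two-sample
  default; with the strong instruments the F check enforces, the omitted
  term is second-order). IVW pools with weights w_j = β̂²_Xj/σ²_Yj,
  equivalent to zero-intercept WLS of β̂_Y on β̂_X with weights 1/σ²_Yj.
  Fixed-effects SE is 1/√Σw; the multiplicative random-effects variant
  (reported automatically when Cochran's Q has p < 0.05) scales it by
  max(1, √(Q/(J−1))). IVW, median and mode use a normal reference.
* **MR-Egger.** Same regression with a free intercept, after orienting
  every pair so β̂_X ≥ 0 (the estimator is invariant to allele orientation
  only after this convention). SEs are the weighted-normal-equation ones
  times max(1, residual scale); inference uses a t reference with J−2 df,
  the convention of the method's literature.
* **Weighted median.** Ratios sorted; the estimate interpolates the
  standardized cumulative weight s_j = (Σ_{i≤j}w_i − w_j/2)/Σw at 0.5.
* **Weighted mode.** Normal-kernel weighted density over the ratios with
  bandwidth 0.9·min(SD, MAD/0.6745)·J^(−1/5) (a modified-Silverman rule;
  `bandwidth_factor` rescales it), maximized on a 1024-point grid spanning
  the ratios ±3 bandwidths. Zero dispersion returns the common ratio. The
  grid makes the estimate deterministic; its resolution (~10⁻³ of the ratio
  range) is far below the estimator's sampling noise.
* **Bootstrap SEs.** Median and mode SEs come from a parametric bootstrap
  (default 1000 draws) resampling β̂_X and β̂_Y from their observed normal
  sampling distributions, with weights recomputed per draw. Every
  stochastic routine requires an explicit seed; there is no global RNG.

## MR-PRESSO

Observed statistic: RSS = Σ_j (β̂_Yj − θ̂₍₋ⱼ₎β̂_Xj)² with θ̂₍₋ⱼ₎ the
leave-one-out IVW estimate. The null distribution redraws β*_X ~ N(β̂_X,
σ_X) and β*_Y ~ N(θ̂₍₋ⱼ₎β̂_X, σ_Y) (default 1000 replicates) and recomputes
the statistic identically. Empirical p-values use (1+#{≥obs})/(n_sim+1) so
they are never zero; per-SNP p-values are Bonferroni-multiplied by J and
capped at 1. A structural consequence: the smallest achievable adjusted
per-SNP p is J/(n_sim+1), so outlier detection at significance 0.05 with
J = 50 requires n_sim ≥ 1000 — the default. The distortion test compares
(θ_raw − θ_corrected)/|θ_corrected| against removing equally many random
SNPs. At least 4 instruments are required. All three tests share one
seeded draw stream, so results are bit-reproducible.

## Multivariable MR

Outcome betas are regressed on the J×E exposure-beta matrix (no intercept,
weights 1/σ²_Y); coefficient SEs come from the weighted normal equations
with a multiplicative overdispersion factor floored at 1 (df J−E). With
one exposure this reproduces the univariable IVW point estimate exactly
and the multiplicative random-effects SE (the floor makes fixed and random
coincide when residual scale ≤ 1). Joint instrument sets take the union of
per-exposure selections, clumped with priority given to each variant's
minimum p across exposures — a package decision that preserves the
strongest signals. Rank-deficient exposure matrices raise an error naming
the collinear exposures. No conditional-F weak-instrument statistic is
computed; that is a known limitation.

## Power

For a case-control outcome GWAS (N, case fraction K) and instruments
explaining R² of the exposure, two power conventions are provided:

* **attenuated** (default): the causal OR is mapped to a risk-difference
  slope b = K(OR/(1+K(OR−1))−1) with sampling variance
  (K(1−K)−b²)/(N·R²); the Wald statistic is referred to a noncentral χ²₁.
  This is the convention of the standard MR power calculators for binary
  outcomes and is the formula under which the package reproduces the
  motivating study's printed minimal ORs.
* **log_or**: power = Φ(|ln OR|·√(N·R²·K(1−K)) − z). This is the *exact*
  power of the IVW z-test when summary statistics live on the log-odds
  scale — i.e., for data from this package's generator — which is why the
  analytic-versus-empirical calibration test uses it.

The two differ materially at low case fractions (the attenuated formula
implies more information per case); both are exposed, with two-sided α the
default and a one-sided switch because published minimal ORs are often
reported without stating sidedness. `min_detectable_or` inverts the power
function by Brent root-finding (xtol 1e-8); closed forms from the normal
approximation are provided as cross-checks.

## Synthetic data

The generator draws summary statistics directly: ƒ_j ~ U(0.05, 0.5),
per-SNP R² uniform within ±50% of total_r2/J, γ_j = √(R²_j/2ƒ_j(1−ƒ_j)),
σ_Xj = 1/√(2n_Xƒ_j(1−ƒ_j)), σ_Yj = 1/√(2n_YK(1−K)ƒ_j(1−ƒ_j)), β̂_X ~
N(γ, σ_X), β̂_Y ~ N(θγ + α, σ_Y). Defaults mirror the motivating study's
best-powered arm: outcome 5,327 cases / 73,884 controls, exposure
n = 300,000, total R² = 8% (the upper end of the per-exposure range
observed there, chosen so recovery tests are well powered). Pleiotropy
modes: `balanced` α ~ N(0, τ²); `directional` α ~ U(0, τ) on a
`prop_invalid` fraction (scenario default τ = 0.1, 40% invalid);
`inside_violating` α = τ·γ (a coherent cluster at ratio θ+τ, maximally
violating InSIDE); `outliers` α = 10·σ_Y on ceil(prop_invalid·J) SNPs.
A mediation preset emits two exposures with complete mediation
(X1 → X2 → Y) for the multivariable attenuation pattern, and an LD-block
generator exists solely to exercise clumping and proxy search.

What the generator does **not** emulate: residual LD between instruments
(a post-clumping world is assumed), sample overlap between exposure and
outcome GWAS, winner's-curse in instrument selection, allele-frequency
mismatch between cohorts, strand errors, or non-normal effect
distributions. Passing tests therefore demonstrate correctness of the
estimators and their documented contracts under the stated sampling model
— not robustness of real-data conclusions to those additional artifacts.

## Problem sizes in the test suite

Calibration checks use 2,000 simulated null studies (J = 50) for type-I
error, 200 studies (J = 100) for bias/coverage, 100 replicates for
MR-PRESSO detection and 200 for its null size, 2,000 studies for
analytic-versus-empirical power, and 1,000 random ≤12-SNP instances for
the clumping brute-force comparison — sizes at which the binomial
uncertainty of each rate sits comfortably inside the asserted band.
Oracle equivalences (IVW, multivariable MR against raw normal equations)
are exact to 10⁻¹⁰. All simulation tests fix their seeds; the full suite
is deterministic.

## Known limitations

Single-SNP analyses report only Wald ratios (no Egger/median/mode, which
need ≥3 instruments). MR-PRESSO needs ≥4. No correction for
exposure-outcome sample overlap is implemented (the overlap scenario can
be simulated, not corrected). Steiger direction filtering, robust/penalized
IVW variants, non-linear MR and mediation-proportion decomposition are out
of scope. The harmonizer never queries remote services; proxies and LD
come from user-supplied local tables.
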