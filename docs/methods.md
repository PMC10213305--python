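# Methods

This note records the statistical model the package implements, the
conventions and defaults it adopts where the literature leaves choices
open, and what its synthetic-data tests do and do not demonstrate.

## Data model and assumptions

All computations start from summary-level GWAS associations: for each
variant j, an exposure effect β̂ₓⱼ with standard error seₓⱼ and an outcome
effect β̂ᵧⱼ with seᵧⱼ, both per copy of a shared effect allele.  The
instrumental-variable assumptions are the usual ones: each instrument is
(i) robustly associated with the exposure, (ii) independent of
confounders of the exposure–outcome relationship, and (iii) affects the
outcome only through the exposure.  The estimators further assume the two
GWAS samples do not overlap (so sampling errors of β̂ₓ and β̂ᵧ are
independent) and that instruments are mutually independent after LD
clumping.  Wald-ratio standard errors use the first-order delta method,
seᵧⱼ/|β̂ₓⱼ|, ignoring exposure-side noise; this is the standard
approximation and is accurate when instruments are strong (F ≫ 10).  A
second-order variant that propagates seₓ is available for Cochran's Q
(`weights="second_order"`) but is off by default, because the first-order
form is what the pooled estimators weight by.

## Estimators

**IVW.**  β̂ = Σwⱼθ̂ⱼ/Σwⱼ with wⱼ = (β̂ₓⱼ/seᵧⱼ)², identical to the
zero-intercept weighted least-squares slope of β̂ᵧ on β̂ₓ with weights
1/seᵧ² (the equivalence is cross-checked in the tests against an
independent WLS route).  The default model is multiplicative random
effects: the fixed-effect SE (Σwⱼ)^(−1/2) is scaled by
σ̂ = √(Q/(k−1)) with σ̂ unconstrained, so the SE can shrink when the
ratios underdisperse.  This choice is deliberate: on the two packaged
cohort tables the unconstrained multiplicative model (σ̂² = 1.25 and
0.56) reproduces the published confidence intervals and p-values, while
the strict fixed-effect formula does not.  p-values are two-sided normal.

**MR-Egger.**  Weighted least squares of β̂ᵧ on β̂ₓ with a free intercept,
weights 1/seᵧ², residual variance estimated on k−2 df and applied
multiplicatively (again unconstrained); slope and intercept p-values are
two-sided t on k−2 df.  This normal/t split (normal for IVW, t for Egger)
is likewise pinned by the published values it reproduces.  Because the
intercept is not invariant to which allele is labelled effect allele, the
fit requires instruments oriented so every exposure effect is positive;
`orient_positive_exposure` establishes that convention and leaves every
Wald ratio unchanged.  Requires k ≥ 3.

**Weighted median.**  Sort the Wald ratios ascending; with normalized
weights w′ⱼ the j-th sorted ratio sits at cumulative probability
sⱼ = Σᵢ≤ⱼw′ᵢ − w′ⱼ/2; the estimate interpolates linearly at s = 0.5.
With equal weights this reduces to the interpolated unweighted median.
The SE is a parametric bootstrap (default n_boot = 1000): resample
(β̂ₓⱼ, β̂ᵧⱼ) from normals centred on the observed values with SDs
(seₓⱼ, seᵧⱼ), recompute the estimator, take the SD across resamples.
The point estimate is deterministic; the SE, CI and p-value depend on the
seed, which the pipeline therefore requires explicitly.

All methods report exp(β̂) with a normal-theory 95% CI
(z = 1.959964); for binary outcomes this is an odds ratio per unit of
exposure.

## Diagnostics

**Cochran's Q** uses the IVW weights and fixed-effect pooled estimate:
Q = Σwⱼ(θ̂ⱼ − β̂)², p from χ²(k−1).  It equals the weighted residual sum
of squares of the zero-intercept regression, which the tests verify
through an independent code path.

**Leave-one-out** re-runs IVW omitting each instrument.  A row is
flagged "influential" when the point estimate changes sign or leaves the
full-set CI.  This flag is a package convention — the underlying
question ("does any single SNP drive the result?") has no canonical
quantitative form.

**MR-PRESSO.**  Observed statistic: RSS = Σⱼ(β̂ᵧⱼ − b₍₋ⱼ₎β̂ₓⱼ)²/seᵧⱼ²,
where b₍₋ⱼ₎ is the fixed-effect IVW slope without SNP j.  Null
distribution: n_sim (default 10,000) parametric draws
βₓ*ⱼ ~ N(β̂ₓⱼ, seₓⱼ), βᵧ*ⱼ ~ N(b₍₋ⱼ₎β̂ₓⱼ, seᵧⱼ), RSS recomputed per
draw; the global p is the add-one tail proportion
(1 + #{RSS* ≥ RSS})/(n_sim + 1), so it is never exactly zero.  Per-SNP
outlier p-values compare each observed weighted residual with its own
simulated distribution, Bonferroni-tested at 0.05/k.  When outliers are
found, the distortion test reports the percent change of the IVW
estimate after their removal, calibrated against removals of random
subsets of the same size (capped at 5,000 draws).  10,000 simulations
resolve a p around 0.5 to Monte-Carlo error ≈ 0.005.  Requires k ≥ 4.

**Funnel data** pairs each ratio with its precision 1/se; asymmetry about
the IVW reference is the visual signature of directional pleiotropy.
The package exports coordinates only (TSV), leaving rendering to any
plotting layer.

## Instrument selection

Defaults follow common two-sample practice: exposure p < 5×10⁻⁸ (strict
inequality throughout), greedy clumping at r² > 0.001 within a 10,000 kb
window (index SNP = smallest p; ties broken by position, then id, so the
result is order-independent), outcome screen at p < 5×10⁻⁸, and proxy
substitution at r² ≥ 0.8 with ties broken by smaller outcome p, then id.
The distance window is enforced exactly when coordinates are present and
skipped otherwise (all pairs treated as in-window); unknown r² inside the
window is treated as above threshold by default ("conservative"), since
an unlisted pair in a sparse LD table is more often unmeasured than
independent — "permissive" is the right setting when the LD table is
known to list only proxy pairs.  LD arrives as a pairwise r² file; the
package performs no reference-panel lookups.

R² per instrument is 2·EAF·(1−EAF)·(β/SD)².  The phenotypic SD of the
exposure is exposed as a parameter (default 1, i.e. standardized betas)
rather than hidden, because variance explained is meaningless without
knowing the scale of β — on the packaged tables, summing the formula at
SD = 1 gives 0.98%, whereas the study-level figure of 0.36% evidently
used a different (unpublished) SD.  The F-statistic follows
((N−k−1)/k)·R²/(1−R²).

## Harmonization conventions

Allele alignment tries, in order: direct match, swapped match
(sign-flip), strand-complemented match, complemented-swapped match;
anything else is excluded as `allele_mismatch`.  Palindromic variants
default to frequency inference with an ambiguity band of EAF ∈
[0.42, 0.58] (excluded inside the band); `drop` and `keep` policies are
available.  None of the packaged instruments is palindromic, so this
choice does not affect the cohort results.  Every exclusion and flip is
logged with a reason code.

## Synthetic generator

`generate` draws γⱼ = |N(0.06, 0.03²)| (positive by orientation
convention, magnitudes matching the packaged exposure betas of
0.036–0.131), seₓ ~ U(0.004, 0.008) and seᵧ ~ U(0.03, 0.10) (the scales
of a ~7×10⁴-person quantitative-trait GWAS and a few-thousand-case
binary-trait GWAS), then β̂ₓⱼ ~ N(γⱼ, seₓⱼ²) and
β̂ᵧⱼ ~ N(θγⱼ + αⱼ, seᵧⱼ²).  Pleiotropy αⱼ is zero, balanced
(mean 0) or directional (mean ≠ 0), optionally correlated with γⱼ to
violate InSIDE.  `generate_with_outliers` adds a fixed shift to the
direct effects of designated SNPs, leaving the base draw untouched so the
zero-outlier case is bit-identical to `generate`.  Only non-palindromic
allele pairs are emitted, and no LD between instruments is simulated
(instruments model the post-clumping state).

What the calibration tests show: fixed-effect IVW CIs cover θ at 95% ± 3%
over 500 null replicates; the Egger intercept recovers a directional
pleiotropy mean within Monte-Carlo resolution when instruments are strong;
MR-PRESSO's global test rejects at ≈ the nominal rate under the null and
flags injected outliers.  What they do not show: robustness to sample
overlap, LD between instruments, allele-frequency mismatch between
cohorts, non-normal effect distributions, or selection effects from
significance thresholding (winner's curse) — none of which the generator
emulates.  Passing these tests therefore validates the estimators under
their own assumptions, not the assumptions themselves.

## Numerical choices and edge cases

* Strict inequalities for every p-value threshold.
* IVW with k = 1 (fixed) reduces exactly to the Wald ratio;
  multiplicative random effects requires k ≥ 2, Egger and the weighted
  median k ≥ 3, MR-PRESSO k ≥ 4; the pipeline degrades gracefully
  (IVW + Q only) below k = 3 and fails with a diagnostic at k = 0.
* β̂ₓ = 0 instruments are dropped at orientation (they carry no
  orientation or causal information); bootstrap/simulation draws that
  cross zero are nudged to the smallest positive float rather than
  discarded, preserving draw counts and hence seed reproducibility.
* Weighted-median interpolation uses a stable sort, making ties
  deterministic.
* The exposure-scale test-statistic sizes in the suite (500 coverage
  replicates at k = 30, 100 intercept-recovery replicates at k = 100,
  200 PRESSO-calibration datasets at 400 simulations) keep the full run
  around ten seconds while leaving Monte-Carlo error well inside the
  asserted bands.

## Known limitations

No mode-based or multivariable estimators, no radial MR, no CAUSE-style
models; no VCF input or liftover; no live LD or phenome lookups (all
reference data arrives as flat files).  The MR-PRESSO distortion test's
random-subset calibration is approximate for very small k, where few
distinct subsets exist.
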