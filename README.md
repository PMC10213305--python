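# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` estimates the causal effect of an exposure on an outcome using
genetic variants as instrumental variables, when all that is available is
summary-level GWAS data (per-SNP effect sizes, standard errors and
p-values from two different cohorts).  It was built around a concrete
epidemiological question — does smoking quantity (cigarettes per day,
CPD) causally affect Alzheimer's disease (AD) risk in East Asian
populations? — and ships the per-SNP instrument tables of that analysis
as built-in fixtures, so the entire workflow runs end to end with no
external downloads.

The package covers:

* **instrument selection** — genome-wide significance filtering
  (p < 5×10⁻⁸), greedy LD clumping (r² > 0.001 within 10,000 kb),
  outcome- and confounder-association screens, LD-proxy substitution
  (r² ≥ 0.8) for instruments missing from the outcome GWAS, and
  instrument-strength statistics R² = 2·EAF·(1−EAF)·(β/SD)² and
  F = ((N−k−1)/k)·R²/(1−R²);
* **harmonization** — aligning exposure and outcome effects onto a shared
  effect allele, with strand-flip resolution and configurable handling of
  palindromic (A/T, C/G) variants;
* **estimation** — per-SNP Wald ratios β̂ᵧⱼ/β̂ₓⱼ pooled by inverse-variance
  weighting (fixed-effect or multiplicative random-effects), MR-Egger
  regression with its intercept test for directional pleiotropy, and the
  weighted median estimator with a parametric-bootstrap SE;
* **sensitivity diagnostics** — Cochran's Q heterogeneity test,
  leave-one-out re-estimation, the simulation-based MR-PRESSO global /
  outlier / distortion tests, and funnel- and forest-plot coordinates;
* **synthetic data** — a generator for two-sample summary statistics
  under the model β̂ₓⱼ ~ N(γⱼ, seₓⱼ²), β̂ᵧⱼ ~ N(θγⱼ + αⱼ, seᵧⱼ²) with
  configurable balanced/directional pleiotropy, InSIDE violations and
  injected outliers, for parameter-recovery and calibration studies.

## The model

Each instrument j gives a Wald ratio estimate θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ with
first-order standard error seᵧⱼ/|β̂ₓⱼ|.  The IVW estimate is the
inverse-variance-weighted mean of the θ̂ⱼ — equivalently the slope of the
zero-intercept weighted regression of β̂ᵧ on β̂ₓ with weights 1/seᵧ².
The default multiplicative random-effects variant scales the fixed-effect
SE by the residual dispersion σ̂ = √(Q/(k−1)), unconstrained.  MR-Egger
frees the intercept of that regression: under InSIDE, the slope remains a
consistent causal estimate and the intercept measures average directional
pleiotropy (inference on t with k−2 df).  The weighted median interpolates
the weight-ordered Wald ratios at 50% of total weight and is consistent
when at least half the weight comes from valid instruments.  For binary
outcomes β̂ᵧ is a log odds ratio, so exp(θ̂) is an OR per unit of exposure.

## Worked example

The 5-instrument CPD→AD analysis for the Chinese case-control cohort,
from the packaged tables:

```python
from tsmr import builtin_fixture, harmonize, orient_positive_exposure
from tsmr import ivw, egger, weighted_median, cochran_q, mr_presso

exposure, outcome = builtin_fixture("chinese")
hset, log = harmonize(exposure, outcome)
hset = orient_positive_exposure(hset)

for est in (ivw(hset), egger(hset), weighted_median(hset, seed=1)):
    print(f"{est.method:<9} OR {est.or_:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})"
          f"  p = {est.pval:.3f}  k = {est.n_snp}")

block = egger(hset).extra["intercept"]
print(f"Egger intercept {block.intercept:.3f} (se {block.se_intercept:.3f}, "
      f"p = {block.pval_intercept:.3f})")
q = cochran_q(hset)
print(f"Cochran's Q = {q.q_stat:.2f} on {q.df} df, p = {q.pval:.3f}")
presso = mr_presso(hset, n_sim=10_000, seed=1)
print(f"MR-PRESSO global p = {presso.global_pval:.3f}, outliers: {presso.outliers or 'none'}")
```

prints

```
IVW       OR 0.512 (0.149-1.760)  p = 0.288  k = 5
MR-Egger  OR 0.225 (0.016-3.141)  p = 0.348  k = 5
WME       OR 0.385 (0.117-1.274)  p = 0.118  k = 5
Egger intercept 0.069 (se 0.098, p = 0.531)
Cochran's Q = 4.98 on 4 df, p = 0.289
MR-PRESSO global p = 0.452, outliers: none
```

Genetically higher smoking quantity shows no significant causal
association with AD (the IVW CI spans OR = 1), all three estimators point
the same way, and none of the pleiotropy diagnostics fires: the Egger
intercept is compatible with zero, Q finds no excess heterogeneity among
the per-SNP ratios, and MR-PRESSO detects no outlying instrument.  (The
WME confidence interval and p-value depend on the bootstrap seed; the
point estimate does not.)

The same workflow is available from the shell:

```
tsmr fixtures --name chinese --out data/
tsmr run --config config.yaml          # selection -> harmonize -> estimate -> diagnose
tsmr simulate --k 100 --theta 0.3 --seed 7 --out sim/
tsmr validate data/chinese_exposure.tsv
```

`tsmr run` writes `results.tsv` / `results.json`, `sensitivity.json`,
`leave_one_out.tsv`, `funnel.tsv`, `forest.tsv`, `exclusions.tsv` and a
`manifest.json` that suffices to replay the run; outputs are
byte-identical for a fixed seed.

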