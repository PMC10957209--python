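# Methods

## The model

`mimicsem` estimates MIMIC (multiple-indicator, multiple-cause) structural
equation models for a single latent outcome. Five observed task scores
y₁…y₅ measure a latent cognitive factor η; p observed brain features
x₁…x_p act as simultaneous causes of the factor:

    y_k = ν_k + λ_k η + ε_k,     ε_k ~ N(0, θ_k)
    η   = Σ_j γ_j x_j + ζ,       ζ   ~ N(0, ψ)

Identification fixes the first loading λ₁ = 1 and leaves the disturbance
variance ψ free; the model-implied χ² is invariant to this choice. The
predictor block is treated as saturated and exogenous (its covariance Φ
and means are freely estimated, hence equal to the sample moments at the
optimum). Because the package's data model confines missingness to the
indicators, the joint likelihood factorizes exactly into a saturated
Gaussian for x and a conditional Gaussian for y given x with mean
ν + λ(γ′x) and covariance ψλλ′ + Θ. Estimation therefore maximizes the
low-dimensional conditional likelihood — this *is* full-information
maximum likelihood for the joint model, at a fraction of the cost.
Reported log-likelihoods, AIC and BIC include the saturated x-block
contribution so comparisons across predictor sets follow the conventions
of standard SEM software.

### Estimation details

* **Sufficient statistics.** Rows are grouped by indicator-missingness
  pattern; per pattern the likelihood and its analytic gradient depend on
  the data only through moment accumulations (Σy, Σyy′, Σx, Σxx′, Σyx′),
  so the optimizer cost is independent of n once the moments are built.
* **Optimizer.** L-BFGS-B on the free parameters with analytic gradients.
  Variances are optimized on the log scale, enforcing nonnegativity
  without active constraints. Convergence: gradient max-norm below 1e-6
  or 5,000 iterations.
* **Start values** are deterministic: loadings from the first principal
  component of the indicator covariance scaled to the reference
  indicator, structural paths at zero, variances at half the sample
  values. Repeated runs are bit-reproducible.
* **Equality constraints** on paths are enforced exactly by parameter
  tying (one free parameter per constrained group), not by penalty.
* **Robust standard errors** use the Huber–White sandwich A⁻¹BA⁻¹ with A
  the observed information (finite differences of the analytic score) and
  B the outer product of casewise scores. Under multivariate normality
  they agree with the information-based SEs; under excess kurtosis
  (scaled-t residuals) the inflation concentrates on the variance
  parameters — with the reference-loading identification the loadings
  themselves remain close to normal-theory efficiency, which is why the
  test suite checks the inflation on θ rather than λ.

### Fit indices

χ² = N·F_min with N the analysis sample size (with incomplete data, χ² is
twice the log-likelihood gap to an EM-estimated saturated model, the FIML
convention). RMSEA = √(max(χ²−df, 0)/(df·N)) with a 90% CI from inverting
the noncentral-χ² distribution; the N (rather than N−1) scaling is used
throughout. CFI/TLI use the independence baseline (all covariances zero,
variances and means free). SRMR is the root mean square of correlation
residuals over the lower triangle including the diagonal. Latent-outcome
R² = 1 − ψ/Var(η); the adjustment 1 − (1−R²)(n−1)/(n−k−1) counts only the
predictor paths k, not all free parameters (the natural reading when the
measurement model is common to every compared model).

## Regularized estimation

The penalized objective is F_ML(θ) + λ_pen·Σ_j |γ_j|, with the penalty on
the structural paths only; loadings and variances stay unpenalized.
Predictors (indeed all variables) must be standardized first — the lasso
is scale-dependent — and unstandardized input is refused rather than
silently rescaled.

The solver alternates two exact blocks:

1. **Measurement block.** With γ fixed, the discrepancy depends on the
   predictors only through the composite c = γ′x, so (λ, θ, ψ) are
   re-optimized in a (q+1)-variable problem independent of p.
2. **Path block.** With the measurement fixed, the discrepancy is an
   exact quadratic in γ: a·γ′S_xx γ − 2b′γ with a = λ′Wλ, b = S_xy Wλ,
   W = (ψλλ′+Θ)⁻¹. Coordinate descent with soft-thresholding solves the
   lasso subproblem exactly, so zeros in the solution are exact zeros
   from the proximal operator, never thresholded small values.

λ_max (the smallest penalty with an all-zero stationary path solution) is
computed from the null-model gradient 2·max_j |b_j| at the γ=0 optimum;
the path runs over a 30-point log-spaced grid from just above λ_max down
to λ_max/1,000 with warm starts. With missing indicator entries the
saturated moments are first estimated by EM (FIML-consistent) and the
penalized model is fitted to those moments; casewise penalized FIML would
cost orders of magnitude more for no change in the estimand.

**Penalty selection** is by BIC over the path. The BIC log-likelihood is
that of the active set refitted *without* shrinkage (the relaxed-lasso
convention), with the parameter count including only the nonzero paths.
The shrunken-estimate log-likelihood systematically favors denser
solutions (the bias of shrunken large effects masquerades as lack of
fit); the relaxed form restores the intended operating characteristics —
in the packaged calibration study (5 true paths of |γ| ≥ 0.15 among 30
predictors, n = 5,000) it retains every true path and at most three false
ones in well over 90% of replicates.

## Stability selection

The regularized selection is repeated over B random subsamples drawn
without replacement (default fraction 0.15, matching a repeated
model-building draw), each iteration standardizing within the subsample,
running the BIC-selected path and recording the exact-nonzero survivor
set. Per-iteration seeds are base_seed + b, so serial and parallel
execution produce identical reports; failed iterations are excluded from
the denominator and counted. Survival percentages rank predictors
concordantly with |true γ| in the packaged calibration (Spearman ρ > 0.7
at n = 5,000, B = 100). Comparing survival between a one-tissue and a
combined context quantifies how much of a region's information becomes
redundant when the other tissue competes.

## Study pipeline

`run_study` splits the sample (⌊0.15·n⌋ building rows — reproducing
1,781/10,095 at n = 11,876 — the floor convention matters), fits the
measurement model on the validation sample, runs one single-predictor
model per (region, metric) for the marginal-effect map, regularizes the
per-metric, per-tissue and combined models on the building sample only,
refits the survivor-defined models unpenalized on the validation sample,
and tests each tissue's contribution by constraining its paths to zero in
the combined model. Survivor sets are a pure function of the building
data (a leakage guard the tests enforce by permuting the validation
rows). The adjusted-R² triple (gray, white, combined) is classified as

* **redundant** if R²_joint ≤ max(R²_g, R²_w) + δ,
* **independent** if R²_joint ≥ R²_g + R²_w − δ,
* **partially overlapping** otherwise,

with δ = 0.01 (the verbal criteria carry no tolerance; 0.01 is half the
smallest gap the classification must resolve in practice). Equality
constraints on paths are applied to unstandardized coefficients of
standardized variables, which coincides with standardized equality given
the preprocessing. TIV enters as an additional predictor on request; sex
stratification reruns the tissue comparison per stratum. Bilateral
averaging is assumed done upstream: the pipeline validates the expected
region counts (34 per gray metric, 20 per white metric) rather than
performing it.

## The synthetic generator

`SyntheticConfig`/`generate_dataset` emulate the statistical structure
the analysis assumes, with archived ground truth (the realized latent
scores and the generating configuration), so every stage is testable
without restricted data.

* **Measurement.** η is standard normal; indicator k = loading_k·η +
  residual with unit total variance. Default loadings (0.74, 0.70, 0.53,
  0.50, 0.41) span the range typical of a broad cognitive battery.
* **Feature covariance.** A nested factor construction: a global factor
  (loading √cross_tissue_rho everywhere), one factor per metric (raising
  same-metric correlations to within_metric_rho) and one per
  (tissue, region) (raising same-region cross-metric correlations to
  cross_metric_rho). The construction is positive definite whenever
  cross_tissue_rho ≤ min(within_metric_rho, cross_metric_rho) and
  within_metric_rho + cross_metric_rho − cross_tissue_rho < 1. Same-tissue
  different-metric different-region pairs sit at the cross-tissue floor —
  the three stated parameters underdetermine that entry, and the floor is
  the minimal choice that preserves positive definiteness by
  construction. Defaults (0.30 / 0.40 / 0.15) give the moderate regional
  and cross-metric dependence typical of parcel-averaged morphometry.
* **Volume composition.** GMV columns are not drawn independently:
  GMV_r = w·(CT_r + SA_r) + τ·noise, rescaled to unit variance, with
  τ = gmv_composition_noise (default 0.30, leaving a ≈0.95 correlation
  with the standardized CT+SA composite) — the near-deterministic
  redundancy of volume with thickness and area.
* **Structure.** η is regenerated as Σγ_j x_j + disturbance scaled so
  Var(η) = 1, making `true_paths` the population standardized effects.
* **Missingness** is MCAR and confined to the cognition columns (default
  rate 0.02, the order of task-level missingness in large batteries), so
  FIML is exercised exactly where the analysis uses it.
* **TIV** is a standardized sum of the volume columns plus noise (a pure
  common-size composite spanned by the predictors); **sex** is an
  independent label (female fraction 0.478).

`population_r2(config, subset)` is the closed-form oracle: with
c = Cov(x_S, η) = Σ_S·γ, the best linear predictor from subset S explains
c′Σ_SS⁻¹c of the unit latent variance. It is monotone under superset
inclusion and drives the scenario factories:

* `partial_overlap_config` scales the two tissue signal patterns and the
  cross-tissue correlation so the population (gray, white, joint) R²
  triple equals (0.154, 0.124, 0.190) — the default study conditions —
  and, when TIV is included, tunes the composite noise so the TIV-only
  R² is 0.068. The signal pattern concentrates effects in a few regions
  per metric with area and volume dominating thickness (gray) and tract
  volume dominating FA and MD (white), including one small negative path
  per tissue.
* `redundant_config` routes all direct effects through gray matter with
  near-ceiling cross-tissue correlation (joint ≈ max).
* `independent_config` zeroes the cross-tissue correlation with disjoint
  signals (joint ≈ sum).

### What the generator does not emulate

Site/scanner effects, non-Gaussian feature distributions, hemispheric
asymmetry (features are already "bilaterally averaged"), missingness in
the brain features, and measurement-model misfit (the synthetic CFA fits
essentially perfectly, so the pipeline's fit indices on synthetic data sit
near their ideal values rather than at the mild misfit real batteries
show). Passing tests therefore demonstrate correctness of the estimators
and the selection machinery under the stated assumptions, not robustness
to the full messiness of consortium imaging data.

## Problem sizes used by the packaged studies

The calibration studies shipped with the package use: parameter recovery,
200 replicates at n = 2,000; selection operating characteristics, 100
replicates at n = 5,000 with 30 predictors; likelihood-ratio null
calibration, 1,000 replicates at n = 400 with Δdf = 3; stability
concordance, B = 100 subsamples at n = 5,000. The acceptance script runs
the full pipeline once at n = 11,876 with B = 50 stability iterations on
the combined model. These sizes give Monte-Carlo error comfortably inside
each check's tolerance.

A practical caveat on scale: the default partial-overlap conditions
spread modest effects over ~19 regions, and BIC-selected paths on
building samples much below ~1,800 rows start missing the weaker
tissue's signals entirely — the survivor-based joint model then degrades
toward the stronger tissue alone and the classification can slip to
"redundant". The pipeline is calibrated for study sizes around
n ≈ 12,000 at the 15% building fraction; with fewer participants, raise
`build_fraction`.

## Known limitations

Single-factor measurement models only; predictors must be complete (only
indicator missingness is handled); no Satorra–Bentler scaled test
statistics (robustness to non-normality is addressed through sandwich
standard errors instead — scaled-χ² correction factors cannot be
validated without the original data); no ridge/elastic-net penalties; no
cross-validated penalty selection; no multi-group invariance testing.
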