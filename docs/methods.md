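# Methods

This note documents the statistical machinery in `dyadlink`, its
assumptions, the synthetic-data conditions under which it is validated,
and the numerical and design choices that were genuinely open.

## Data model

The analysis unit is a parent–offspring dyad: one row per pair holding
UCLA-3 loneliness items for mother, father and offspring; five offspring
mediators (subjective socioeconomic ladder 1–10, EAS sociability 1–5,
a continuous cognitive composite, BDI depressive total, GAD-7 anxiety
item-mean 0–3); and nine shared covariates (both generations' ages,
offspring sex, marital status, number of children, number of siblings,
education years, parental education years, income on a 21-point scale).

## Scale scoring

UCLA-3 items are coded 1–3 and summed (range 3–9); a total of at least
6 — the conventional 5/6 cut-off — classifies a respondent as lonely.
The parental exposure is the mean of the two parents' totals,
classified with the same cut-off; when only one parent responded, the
mean degenerates to that parent's total. A scale with any missing item
yields a missing score: no prorating, because missingness is handled at
the variable level by multiple imputation, and prorated part-scores
would distort the imputation model. GAD-7 anxiety is aggregated as the
item mean (range 0–3) rather than the sum: cohort descriptives with
anxiety means well below 1 are only consistent with mean scoring. BDI
items are coded 0–3 (the instrument standard); the item range is a
`ScaleSpec` field, so alternative codings are one argument away.

## Mediation estimator

For binary exposure A (parental loneliness class), continuous mediator
M and binary outcome Y (offspring loneliness class), two models are
fitted on the same analysis rows:

    M = β₀ + β₁ A + β₂ᵀC + ε,  ε ~ N(0, σ²)
    logit P(Y=1) = θ₀ + θ₁ A + θ₂ M + θ₃ A·M + θ₄ᵀC

Without interaction (θ₃ = 0) the natural effects for the contrast
a* = 0 → a = 1 are `log OR_NDE = θ₁`, `log OR_NIE = θ₂ β₁`, and the
total effect is their sum, making `OR_TE = OR_NDE · OR_NIE` an exact
identity of the estimator. With interaction,

    log OR_NDE = [θ₁ + θ₃(β₀ + β₁a* + β₂ᵀc + θ₂σ²)](a−a*)
                 + ½ θ₃² σ² (a² − a*²)
    log OR_NIE = (θ₂ β₁ + θ₃ β₁ a)(a − a*)

reported at covariate values c = the sample means of the analysis rows
(overridable). These OR-scale natural effects approximate
risk-ratio-scale effects; with an outcome prevalence near 29% the
approximation is moderate, and the package reports ORs throughout, as
is conventional for logistic outcome models.

**Delta-method CIs.** Each log effect is differentiated analytically
with respect to the stacked coefficient vector (β, θ); the covariance
is block diagonal because the two models are fitted separately
(cross-model covariance set to zero), and σ² is treated as fixed — its
sampling variability is omitted, a standard simplification whose effect
is O(1/n) relative to the coefficient variances. In the no-interaction
case this reproduces the closed forms
`Var(log NDE) = Var(θ₁)`,
`Var(log NIE) = θ₂²Var(β₁) + β₁²Var(θ₂)`, and
`Var(log TE) = Var(θ₁) + θ₂²Var(β₁) + β₁²Var(θ₂) + 2β₁Cov(θ₁,θ₂)`.
The test suite verifies the general gradient path against these closed
forms and against a nonparametric bootstrap (500 resamples, agreement
within 15% relative at n = 2000).

**Proportion mediated.** `PM = OR_NDE (OR_NIE − 1)/(OR_TE − 1)`;
negative under inconsistent mediation; undefined (reported as missing)
at a null total effect. Recomputing PM from rounded two-decimal ORs can
differ from the value computed on unrounded internals by ~0.01 in the
second decimal, so tests compare with tolerance.

**Interaction screen.** Before decomposing, the pipeline fits the
outcome model with the exposure×mediator product term and reports the
two-sided Wald p-value (pooled over imputations); the no-interaction
estimator is used when the screen is not significant at 0.05
(configurable). An exposure×sex screen is reported the same way.

## Multiple imputation

Chained equations, implemented directly (not a wrapper): columns are
visited in ascending order of missingness for 10 burn-in cycles per
dataset (both conventional defaults); continuous columns use a proper
Bayesian linear draw with predictive mean matching (k = 5 donors;
parametric normal draws optional), binary columns a logistic draw.
Initial values are random draws from each column's observed values.
m = 5 datasets are produced, each from its own seeded stream derived
from the stack seed and the dataset index. The outcome is never
imputed (rows with missing outcome keep it missing), and loneliness
variables are excluded from predictor sets; the exclusion list is a
parameter. Pooling uses Rubin's rules with the classical degrees of
freedom `(m−1)(1 + W/((1+1/m)B))²` (not the Barnard–Rubin small-sample
correction — simpler, stated, and testable), capped when B = 0.
Mediation over a stack pools the *log-scale* effects and their delta
variances, then exponentiates; the product identity survives pooling
because pooled log TE is the mean of per-dataset sums.

## E-values

`E = RR + √(RR(RR−1))` for RR ≥ 1, reciprocal for protective effects.
Because the analysis outcome is common (~29%), odds ratios are
converted by RR ≈ √OR by default; the OR-as-RR convention for rare
outcomes is exposed as an option, since neither convention is uniquely
canonical for moderately common outcomes. CI E-values use the interval
limit nearer the null and equal 1 when the interval crosses 1.

## Synthetic cohort: what it emulates

Defaults were fixed once, to make the generator's output recognizably
like a two-generation questionnaire cohort of ~1000 pairs:

- n = 991 pairs; offspring lonely prevalence calibrated to 29% by
  solving the outcome intercept so the cohort's mean outcome
  probability equals the target exactly.
- Confounder marginals: offspring age N(47, 4.7²), parent age
  N(74, 5.7²) (both truncated), sex Bernoulli(0.563), marital
  Bernoulli(0.766), children Poisson(3.0), siblings Poisson(2.3),
  education N(16, 3.7²), parental education N(11, 3.2²), income
  round(N(9.7, 4.9²)) clipped to 1–21.
- Parent availability: mother 88.1%, father 57.9%, at least one parent
  per pair — which is what makes the per-exposure sample sizes differ
  (≈991/873/574) without imputing the exposure.
- Parent lonely prevalence 0.25 per parent. No published figure exists
  for the parent generation, so this is a free parameter set once to a
  plausible old-age prevalence.
- Planted structural effects: mediator exposure effects β₁ of
  −0.33 (ladder), −0.08 (sociability), 0.05 (cognition), 1.76
  (depressive), 0.08 (anxiety) with residual SDs 1.6/0.7/2.3/5.5/0.33;
  outcome direct effect θ₁ = log 1.51; per-unit mediator log-ORs sized
  so the mental-health indirect paths dominate; covariate log-ORs of
  typical adjusted-model size (e.g. marital −0.89, income −0.062).
- Missingness: per-column rates echoing questionnaire gaps (heaviest
  on the cognitive composite, 9.4%, and depressive total, 6.5%);
  MAR by default, driven by always-observed covariates (offspring age
  and sex) through a logistic link whose intercept is solved to hit the
  marginal rate — deliberately matching the imputation model's
  assumptions so recovery tests are fair. MCAR is available.
- Items are back-filled from scale totals deterministically (integer
  base plus remainder spread left to right): reproducibility over
  realism. Offspring totals are drawn uniformly within the class
  consistent with the drawn outcome.

What it does **not** emulate: genetic transmission, cohort attrition,
longitudinal waves, item-level response styles, skewed symptom
distributions (mediators are linear–normal by construction, except
that bounded instruments — ladder, anxiety, sociability — are
rounded/clipped to their support, which slightly perturbs their
structural coefficients; the unbounded composites carry the sharp
parameter-recovery tests). Passing tests therefore demonstrate that
the estimators recover effects under the stated structural model, not
that they are robust to real-data pathologies outside it.

## Numerical choices

- Logistic fits: maximum likelihood via iteratively reweighted least
  squares (statsmodels), Wald covariance from the observed
  information; perfect or quasi-complete separation is detected
  (non-finite or runaway coefficients) and raised, never returned.
- Rank-deficient designs fail with the offending column named; inside
  the imputation sampler collinear predictors are instead dropped with
  a warning, since a chained-equation sweep must not abort mid-chain.
- Wald (not profile-likelihood) CIs throughout, `exp(coef ± 1.96·SE)`,
  keeping the delta-method composition internally consistent.
- Group descriptives: Welch two-sample t-test for continuous
  variables, chi-square without continuity correction for binary ones.
- Tjur R² = mean fitted probability among cases minus controls; over
  an imputed stack the per-dataset values are averaged.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator` streams; no global state. Identical
  configurations produce byte-identical output bundles (CSV floats are
  written in shortest round-trip form and parsed with round-trip
  precision).
- The continuous-loneliness sensitivity option replaces the
  dichotomized exposure with the raw score (a one-point contrast) while
  keeping the binary outcome; the complete-case option drops exactly
  the rows with any missing analysis column and skips imputation.
- Mother/father exposure variants subset to pairs with that parent
  observed and re-run the whole chain (including imputation) on the
  subset.

## Problem sizes used in validation

The test suite validates at sizes chosen to keep Monte-Carlo error
well inside the asserted bands: closed-form oracles on toy inputs;
single-fit recovery at n = 50,000–100,000; delta-CI coverage and
null-interaction calibration over 200 replicates of n = 2000 cohorts;
imputation recovery at n = 3000–5000 with 20% deletion; bootstrap
comparison with 500 resamples at n = 2000. The acceptance script runs
the full pipeline at the default n = 991.

## Known limitations

- Natural effects are identified only under the usual sequential
  ignorability assumptions (no unmeasured exposure–outcome,
  mediator–outcome or exposure–mediator confounding, and no
  exposure-induced mediator–outcome confounders); the package
  quantifies sensitivity via E-values but cannot test the assumptions.
- OR-scale effects are non-collapsible; effects conditional on
  different covariate sets are not directly comparable.
- One mediator at a time: mediators are decomposed separately, so the
  per-mediator proportions mediated need not sum to anything
  interpretable when mediators are correlated.
- The classical Rubin degrees of freedom can be anti-conservative for
  very small n; with ~1000 rows and m = 5 this is immaterial.
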