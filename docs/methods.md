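# Methods

## The model

`brainagekit` estimates a subject's biological brain age from gray-matter
(GM) probability features and relates the resulting gap to lifestyle.  The
chain is:

1. **Feature reduction.** GM features (voxel-level probabilities in real
   data; simulated probabilities here) are reduced by PCA.  The retained
   dimension defaults to the components explaining 95% of training-set
   variance, capped at (training size − 1); a fixed `k` can be requested
   instead.  PCA is refit inside every cross-validation training fold —
   held-out subjects never influence their own reduction.

2. **Relevance vector regression (RVR).** Age is regressed on the reduced
   features by sparse Bayesian regression: weights carry priors
   `w_i ~ N(0, α_i⁻¹)`, noise has precision `β`, and `(α, β)` maximize the
   marginal likelihood via the fixed-point updates
   `γ_i = 1 − α_i Σ_ii`, `α_i = γ_i / μ_i²`,
   `β = (N − Σ γ_i) / ‖y − Φμ‖²`, pruning any basis function whose
   `α_i` exceeds 1e9 (the bias column is exempt).  Convergence: maximum
   relative change of `α` below 1e-6 (1e-4 inside cross-validation, where
   the extra precision is irrelevant to predictions), at most 1000
   iterations; non-convergence is recorded on the model and the best
   iterate returned.  `β` is capped at 1e12 so noise-free problems stay
   finite.  For the **linear kernel** (the default) the model is fit in
   the primal basis `[1, X]`: a linear kernel spans exactly the affine
   functions of the input, so this is the same model as the n × n kernel
   expansion at a fraction of the cost.  The **RBF kernel** uses the full
   relevance-vector expansion over training points and reports the
   retained relevance vectors.

3. **Leave-10-out, sex-split cross-validation.** Within each sex, subjects
   are shuffled once with the run seed and chunked into consecutive folds
   of k = 10 (remainder → a smaller final fold).  Each fold is predicted
   by a model trained on the rest of its stratum only.  Every subject
   receives exactly one estimate.

4. **Gap and detrend.** `raw gap = estimated − chronological age`.  Brain
   age models regress toward the training mean, which leaves an age trend
   in the gaps; a least-squares fit of the gap on `{1, age, age²}` over
   the full estimation cohort is removed (one extra least-squares
   refinement keeps orthogonality at the 1e-8 level despite the `age²`
   column's scale).  The residual — the BrainAGE score — is exactly
   zero-mean and orthogonal to age and age² on the detrending sample; the
   same coefficients apply unchanged to any subsample.  Detrending is
   pooled across sexes.

5. **Inference.** Ordinary least squares (statsmodels) of BrainAGE on a
   lifestyle term plus covariates, under three treatments of chronological
   age: (1) age as a predictor, (2) age omitted, (3) age regressed out of
   BrainAGE first (residual outcome).  Reported per model: unstandardized
   `b`, standardized `β = b·sd(x)/sd(y)`, t, p, model F and R², the ΔR²
   attributable to the lifestyle term (full minus covariates-only R² on
   identical rows), and residual MAE.  Slopes convert to months of brain
   age per exposure unit as `b × 12`.  The 15-test family (5 lifestyle
   terms × pooled/male/female) is gated at Bonferroni `0.05/15 ≈ 0.003`.

## Lifestyle exposures and the combined risk score

* Pack-years = years smoked × (cigarettes/day ÷ 20).  The package uses the
  standard pack normalization; a `literal=True` flag computes the raw
  years × cigarettes product for comparison with questionnaire conventions
  that skip it.
* Alcohol = Σ serving volume × alcohol fraction × 789 g/L × servings per
  month.  Beverage fractions (beer 0.048, wine 0.11, spirits 0.33 by
  volume) and serving sizes (0.2 l; spirits 0.02 l) are conventions,
  exposed as constants.
* Social integration = 2·(partnered) + children + close relatives +
  friends + active memberships.  No cap is applied to the close-ties sum.
* Physical activity = Σ MET × hours over at most four reported
  activities.  The instrument window is a reporting month; the score is
  treated as MET-hours per reporting window throughout (source
  questionnaires are inconsistent between "per week" and "per month"; the
  regression slope is per MET-hour either way).

The combined score z-transforms each exposure on the fitting cohort,
reverses the protective signs, and shifts: risk components `z − min z`
(≥ 0), protective components `(−z) − max(−z)` (≤ 0); the sum is the
score.  A subtlety: shifting by *adding* the minimum z (which is negative)
would not produce non-negative risk components and yields an expected mean
around −3.4 for the reference descriptives, incompatible with the
published scale of the score (≈ −1.0); subtracting the minimum reproduces
it (closed-form expectation −1.05).  The subtraction form is therefore
implemented.  Transform constants are fit once and persisted; scoring new
subjects reuses them — no silent refit.

## The synthetic cohort generator

The generator defines the study conditions for all simulation-based tests.

* Ages uniform on [18.5, 87.0] years; sex Bernoulli(0.55 male).
* Lifestyle marginals (mean, SD, min, max): pack-years (13.61, 21.73, 0,
  204), alcohol g/month (11.25, 19.87, 0, 198.5), MET score (14.32,
  20.94, 0, 196), social index (12.99, 6.40, 3, 53) — the descriptives of
  the older population-based cohort this pipeline targets.  Draws come
  from truncated normals; an optional correlation matrix induces
  dependence through a Gaussian copula (default: independent, since joint
  moments are not published).
* **Truncation adjustment.** A normal truncated at a finite lower bound
  cannot exceed a coefficient of variation of 1 (its exponential limit),
  while the zero-piled exposures above have CV up to 1.8.  The generator
  therefore solves for parent (μ, σ) such that the *truncated* mean equals
  the configured mean exactly and the truncated SD is the closest the
  family allows (≈ the mean for the zero-bounded variables).  Calibration
  tests assert sample moments against these achievable adjusted moments.
  Consequence: the synthetic exposures are less skewed than real ones and
  contain no exact zeros (no structural never-smoker group); tests of the
  smoker-group contrast construct zero-inflated inputs explicitly.
* Latent brain-age offset (years):
  `offset_i = Σ_v effect_months_v/12 · (x_iv − mean_v) + N(0, 3²)`.
  Default effects: +0.6 months/pack-year, −0.55 months/MET unit, 0 for
  alcohol and social integration — the effect pattern this pipeline is
  designed to detect; the 3-year noise SD reflects the unexplained
  inter-individual spread of gap scores in adult cohorts.
* GM features: `clip₀¹(base_j + L_j·g(age + offset) + ε)`, with
  `g(a) = −0.002·a − 2·10⁻⁵·a²` (strictly decreasing over the adult
  span), baselines base_j ~ U(0.65, 0.85) and loadings L_j ~ U(0.6, 1.4)
  fixed by the config seed, 64 features, feature noise SD 0.02.  The
  quadratic term deliberately makes the linear-kernel estimator's raw gap
  carry a quadratic age trend — exactly the artefact the quadratic
  detrend exists to remove.  The clipping rate is recorded on the cohort.
* What the generator does **not** emulate: voxel topology and spatial
  correlation, segmentation/registration artefacts, site or scanner
  effects, heavy-tailed exposure distributions, exposure–covariate
  confounding (education, BMI and DemTect are drawn independently of the
  exposures).  Passing tests therefore demonstrate the correctness of the
  estimator and inference machinery under known ground truth — not the
  effect sizes or error rates to be expected on real cohort data.

## Numerical and design choices

* Sex is coded female = 0, male = 1 in all models; F-tests are invariant
  to the coding.
* 3-SD outlier rule: mean and SD (population form) computed once on the
  full vector, no iteration; a value exactly at the 3-SD boundary counts
  as an outlier.  By default the rule applies to the lifestyle term(s) of
  the model being fit.
* ANCOVA effects (smoker group, sex interaction) are tested by nested OLS
  model comparison — with a single multi-level factor and no factor
  interactions this equals the Type III sum of squares.  Partial η² =
  SS_effect/(SS_effect + SS_error).  The multivariate variant of the
  covariate screen is out of scope; per-outcome univariate F-tests are
  reported instead (documented limitation).
* Smoker matching: never (pack-years = 0), moderate (< 20), severe
  (≥ 20); nearest-neighbour age matching without replacement within sex,
  caliper 2 years, reference group = smallest, seeded ordering, ties
  broken by subject id.  The matching algorithm behind the published
  grouping is unstated; this is the package's choice.
* Power: noncentrality `λ = f²·n`, numerator df = 1 (the single tested
  lifestyle predictor inside the 5-predictor model), denominator df
  `n − p − 1`.  This is the GPower "R² increase" variant and reproduces
  the published values (0.9952, 0.9774, 0.9998 for f² = 0.05, 0.04, 0.07
  at n = 622, α = 0.003 — printed as 0.99/0.97/0.99); the
  deviation-from-zero variant (numerator df = p) is available through
  `tested_df`.  `f² = 0` returns exactly α.
* Degenerate inputs: zero-variance exposures, all-equal ages, single-sex
  interaction data, empty smoker groups and non-finite design matrices
  raise errors naming the offending quantity; undefined correlations are
  flagged, never silently zeroed.
* p-values are two-sided; missing data are handled by listwise deletion
  (complete-case analysis).

## Problem sizes used in the shipped checks

The simulation-based tests run at sizes chosen to make their statistical
assertions sharp while keeping the default suite fast: calibration and
null-correlation checks at n = 4000–5000; cross-validated estimation
checks at n = 300–1000; parameter recovery across 50 seeds at n = 600
(asserting the 2-SE criterion in ≥ 90% of seeds); type-I error over 500
null cohorts of n = 150 (asserting a rejection rate in [0.03, 0.07]); the
pipeline-level null check over 50 seeds at n = 140.  The acceptance script
reports the mean detrended BrainAGE of a full n = 1000 sex-split
leave-10-out run.

## Known limitations

* The RVR evidence surface is multimodal in general; the fixed-point
  iteration finds a local maximum.  On the small well-conditioned bases
  used in the oracle tests it coincides with the global grid maximum.
* The quadratic detrend is a whole-sample correction; per-sex detrending
  is not implemented (pooled by default, matching the whole-sample
  correction the pipeline targets).
* Real-cohort quantities (MAE ≈ 4.6 y on real GM maps, specific published
  regression tables) depend on data that is not redistributable; the test
  suite substitutes property-based checks with known ground truth.
* NIfTI ingestion is limited to flattening per-subject 3-D GM maps with a
  probability threshold mask; no spatial preprocessing is performed.
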