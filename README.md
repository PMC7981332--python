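# brainagekit

Brain-age gap estimation and combined lifestyle risk analysis for
population-based neuroimaging cohorts.

Structural brain aging varies widely between people of the same
chronological age.  A machine-learning model trained on gray-matter (GM)
probability maps can estimate a brain's *biological* age; the gap

```
BrainAGE = estimated age − chronological age
```

is positive for older-looking (accelerated) and negative for
younger-looking (decelerated) brains.  `brainagekit` implements the full
analysis chain used to ask whether everyday lifestyle — smoking, alcohol,
physical activity and social integration — predicts that gap, and it ships
a synthetic cohort generator with known ground-truth effects so that every
stage can be exercised and tested without access to any real cohort data.

It is aimed at researchers in imaging epidemiology and biostatistics who
want a tested, scriptable reference implementation of this pipeline: the
estimator, the risk score, the inference layer, and the simulation harness
that validates them.

## What is implemented

* **Synthetic cohorts** (`brainagekit.synthdata`) — ages uniform over the
  adult span (18.5–87 y), sex-split, four lifestyle exposures drawn from
  calibrated truncated normals, and GM features whose expectation declines
  (linearly + quadratically) with *effective* age = age + a latent,
  lifestyle-driven offset.  The offset enters the features only through
  anatomy, so downstream estimators can recover it only the honest way.
* **Lifestyle exposures and risk score** (`brainagekit.lifestyle`) —
  pack-years (years × cigarettes/day ÷ 20), grams of ethanol per month,
  a Berkman-style social integration index, MET-hours of activity; the
  combined score sums shifted, sign-aligned z-scores: risk components
  `z − min z ≥ 0`, protective components `(−z) − max(−z) ≤ 0`.
* **Brain-age estimation** (`brainagekit.brainage`) — PCA reduction
  (default 95% variance) followed by relevance vector regression: sparse
  Bayesian regression with per-weight precisions `α_i`, noise precision
  `β`, fit by iterative evidence maximization with pruning (Tipping-style
  updates `γ_i = 1 − α_i Σ_ii`, `α_i = γ_i/μ_i²`,
  `β = (N − Σγ)/‖y − Φμ‖²`).  Estimation is sex-split leave-10-out:
  every subject's age is predicted by a model fit without that subject.
  Raw gaps are detrended for a least-squares quadratic age trend.
* **Inference** (`brainagekit.inference`) — the three age-handling
  approaches (age as predictor / omitted / regressed out of the outcome),
  standardized β, ΔR² of the lifestyle term, residual MAE, 3-SD outlier
  masking, sex × lifestyle interaction ANCOVA, stratified refits,
  linear-vs-quadratic curve comparison, never/moderate/severe smoker
  contrast with age matching, Bonferroni gating (α/15), and noncentral-F
  power with `λ = f²·n`.
* **Pipeline + CLI** (`brainagekit.pipeline`, `brainagekit` console
  script) — simulate → score → estimate → analyze → report with YAML
  configs, CSV/HDF5/JSON outputs and a provenance block (config hash,
  seed, version) in every report.

## Worked example

```python
from brainagekit.synthdata import SimulationConfig, generate_cohort
from brainagekit.brainage import (leave_k_out_estimate, compute_brainage,
                                  detrend_quadratic, performance_report)

cohort = generate_cohort(SimulationConfig(n_subjects=600, seed=3))
ages = cohort.phenotypes["age"].to_numpy()
est, plan = leave_k_out_estimate(cohort.phenotypes, cohort.features,
                                 k=10, sex_split=True, seed=3)
brainage, coef = detrend_quadratic(compute_brainage(est, ages), ages)
report = performance_report(ages, est, brainage)
```

prints (via `python examples/03_brain_age_estimation.py`):

```
MAE = 2.50 years, r(chronological, estimated) = 0.98, R^2 = 0.97
mean BrainAGE = 0.00 (zero by construction of the detrend)
corr(BrainAGE, latent true offset) = 0.96
```

MAE is the mean absolute detrended gap — each subject's gap doubles as the
estimation error for that subject.  The mean BrainAGE of 0.00 is a
property of the least-squares detrend; the 0.96 correlation with the
generator's latent offset shows the estimator reading the injected signal
out of the anatomy alone.  Running the regression layer on the same cohort
(`examples/04_lifestyle_regressions.py`) recovers the injected smoking
effect as +0.66 months of brain age per pack-year (β = 0.25, significant
past the Bonferroni threshold 0.05/15 ≈ 0.003), while alcohol and social
integration — simulated with zero effect — stay non-significant.

The `examples/` directory holds one short script per capability
(simulation, risk scoring, estimation, regressions, smoker groups and
power); each prints the numbers it computes and one line on what they
mean.

## Command line

```sh
brainagekit simulate --n 1000 --seed 1 --out data/
brainagekit estimate --phenotypes data/phenotypes.csv \
    --features data/features.h5 --k 10 --sex-split --seed 1 --out run/
brainagekit analyze --phenotypes data/phenotypes.csv \
    --features data/features.h5 --approach 1,2,3 --covariates sex \
    --alpha 0.05 --family 15 --out run/
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
the limits of what the synthetic cohorts can show about real data.
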