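"""Estimate brain age by sex-split leave-10-out cross-validation.

Within each sex, PCA is refit on every training fold and a relevance vector
regression maps the reduced gray-matter features to age.  The raw gap
(estimated - chronological) is detrended for a quadratic age trend; the
detrended gap is the BrainAGE score (positive = older-looking brain).
"""

import numpy as np

from brainagekit.brainage import (
    compute_brainage,
    detrend_quadratic,
    leave_k_out_estimate,
    performance_report,
)
from brainagekit.synthdata import SimulationConfig, generate_cohort

cohort = generate_cohort(SimulationConfig(n_subjects=600, seed=3))
ages = cohort.phenotypes["age"].to_numpy()

estimated, plan = leave_k_out_estimate(cohort.phenotypes, cohort.features,
                                       k=10, sex_split=True, seed=3)
raw = compute_brainage(estimated, ages)
brainage, coef = detrend_quadratic(raw, ages)
report = performance_report(ages, estimated, brainage,
                            strata=cohort.phenotypes["sex"].to_numpy())

print(f"MAE = {report.mae:.2f} years, "
      f"r(chronological, estimated) = {report.r_chron_estimated:.2f}, "
      f"R^2 = {report.r2_estimated_on_chron:.2f}")
print(f"mean BrainAGE = {report.mean_brainage:.2f} "
      f"(zero by construction of the detrend)")
for sex, sub in report.by_stratum.items():
    print(f"  {sex}: MAE {sub.mae:.2f}, r {sub.r_chron_estimated:.2f}, "
          f"n {sub.n}")
r = np.corrcoef(brainage, cohort.true_offset)[0, 1]
print(f"corr(BrainAGE, latent true offset) = {r:.2f} -- the estimator reads "
      "the simulated offset out of the anatomy alone.")
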