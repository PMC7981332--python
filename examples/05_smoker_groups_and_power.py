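"""Smoker-group contrast and noncentral-F power for the regression models.

Never (0 pack-years), moderate (< 20) and severe (>= 20) smokers are
age-matched within sex and compared by ANCOVA.  Power is evaluated for the
applied 5-predictor regression at the Bonferroni-corrected alpha.
"""

import numpy as np

from brainagekit.inference import (
    PowerRequest,
    compute_power,
    smoker_group_analysis,
)
from brainagekit.synthdata import SimulationConfig, generate_cohort

# a cohort with a zero-inflated smoking distribution so a never group exists
cohort = generate_cohort(SimulationConfig(n_subjects=600, seed=9))
pheno = cohort.phenotypes.copy()
rng = np.random.default_rng(9)
never = rng.random(len(pheno)) < 0.4  # ~40% lifetime non-smokers
pheno.loc[never, "pack_years"] = 0.0
pheno["brainage"] = (cohort.true_offset
                     + 0.05 * (pheno["pack_years"] - pheno["pack_years"].mean()))

res = smoker_group_analysis(pheno, seed=9)
print("matched group sizes:", res.group_counts)
print("adjusted mean BrainAGE:",
      {k: round(v, 2) for k, v in res.adjusted_means.items()})
print(f"group effect: F({res.df_num},{res.df_den}) = {res.f_value:.2f}, "
      f"p = {res.p:.4g}")
print("Severe smokers' brains should look oldest after adjusting for sex, "
      "age and education.\n")

for f2 in (0.04, 0.05, 0.07):
    res_p = compute_power(PowerRequest(f2=f2, n=622, alpha=0.003,
                                       total_predictors=5, tested_df=1))
    print(f"power at f^2={f2:.2f}, n=622, alpha=0.003: {res_p.power:.2f} "
          f"(lambda={res_p.noncentrality:.1f})")
print("Small lifestyle effects are detectable with >= 0.97 power at this "
      "sample size even after multiple-comparison correction.")
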