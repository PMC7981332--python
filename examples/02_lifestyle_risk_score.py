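"""Derive lifestyle exposures from raw inputs and build the combined risk
score.

Each exposure is z-transformed on the cohort; protective behaviours are
sign-reversed and all components are shifted so risk components are >= 0
and protective ones <= 0.  The sum is the combined lifestyle risk score
(higher = riskier, 0 = balance).
"""

from brainagekit.lifestyle import (
    ActivityRecord,
    BeverageIntake,
    SmokingHistory,
    SocialProfile,
    combined_risk_score,
    compute_alcohol_g_month,
    compute_met_score,
    compute_pack_years,
    compute_social_index,
)
from brainagekit.synthdata import SimulationConfig, generate_cohort

print("-- single-subject derivations --")
print("pack-years (10 y, 20 cig/day):",
      compute_pack_years(SmokingHistory(10, 20)))
print("alcohol g/month (30 beers of 0.2 l at 4.8%):",
      round(compute_alcohol_g_month([BeverageIntake("beer", 30)]), 1))
print("social index (partnered, 2 children, 3 relatives, 5 friends, 1 club):",
      compute_social_index(SocialProfile(True, 2, 3, 5, 1)))
print("MET score (7 MET x 4 h + 3.5 MET x 8 h):",
      compute_met_score([ActivityRecord(7, 4), ActivityRecord(3.5, 8)]))

print("\n-- cohort-level combined risk score --")
cohort = generate_cohort(SimulationConfig(n_subjects=1000, seed=1))
result = combined_risk_score(cohort.phenotypes[
    ["pack_years", "alcohol_g_month", "met_score", "social_index"]])
print(f"mean combined risk = {result.score.mean():.2f} "
      f"(SD {result.score.std():.2f})")
print("A negative mean indicates on-average protective behaviour; the score "
      "rises with smoking and drinking and falls with activity and social "
      "integration.")
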