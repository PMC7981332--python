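"""Regress BrainAGE on lifestyle under the three age-handling approaches.

Approach 1 keeps chronological age as a predictor, approach 2 omits it, and
approach 3 regresses age out of BrainAGE before modelling.  Slopes are
converted to months of brain age per exposure unit (slope x 12).
"""

from brainagekit.inference import (
    ModelSpec,
    bonferroni_alpha,
    fit_lifestyle_model,
    quantify_months,
)
from brainagekit.pipeline import PipelineConfig, run_pipeline
from brainagekit.synthdata import SimulationConfig

cfg = PipelineConfig(output_dir="scratch/example_run",
                     simulate=SimulationConfig(n_subjects=600, seed=3),
                     seed=3)
bundle = run_pipeline(cfg)
pheno = bundle.phenotypes

threshold = bonferroni_alpha(0.05, 15)
print(f"Bonferroni threshold for the 15-test family: {threshold:.4f}\n")
for term in ("risk_score", "pack_years", "met_score"):
    for approach in (1, 2, 3):
        fit = fit_lifestyle_model(
            pheno, ModelSpec(approach=approach, lifestyle_terms=(term,),
                             covariates=("sex",)))
        tr = fit.lifestyle()
        months = quantify_months(tr.b)
        flag = "*" if tr.p < threshold else " "
        print(f"{term:>16} approach {approach}: beta={tr.beta:+.3f} "
              f"p={tr.p:.4f}{flag} dR2={fit.delta_r2:.3f} "
              f"-> {months:+.2f} months/unit")
print("\nStarred rows survive the family-wise correction.  The injected "
      "effects (smoking +0.6, activity -0.55 months/unit) should be "
      "recovered; alcohol and social integration carry no effect.")
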