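import logging

import numpy as np
import pandas as pd
import pytest

from brainagekit.synthdata import SimulationConfig, generate_cohort

logging.getLogger("brainagekit").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject cohort with the default (effect-carrying) generator."""
    return generate_cohort(SimulationConfig(n_subjects=300, seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort whose latent brain-age offset is pure noise."""
    cfg = SimulationConfig(
        n_subjects=300, seed=43,
        effect_months={k: 0.0 for k in
                       ("pack_years", "alcohol_g_month", "met_score",
                        "social_index")},
    )
    return generate_cohort(cfg)


@pytest.fixture()
def analysis_frame(small_cohort):
    """Phenotypes with a synthetic BrainAGE outcome (latent offset)."""
    df = small_cohort.phenotypes.copy()
    df["brainage"] = small_cohort.true_offset
    return df


def make_regression_frame(n: int, seed: int, slope: float = 0.0,
                          noise_sd: float = 3.0) -> pd.DataFrame:
    """Minimal frame for inference tests: lifestyle with a known slope."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(56, 85, n)
    sex = rng.integers(0, 2, n).astype(float)
    education = rng.integers(1, 11, n).astype(float)
    lifestyle = rng.normal(0.0, 2.0, n)
    y = slope * lifestyle + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({
        "age": age, "sex": sex, "education": education,
        "lifestyle": lifestyle, "brainage": y,
    })
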