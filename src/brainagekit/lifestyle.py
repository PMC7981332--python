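"""Lifestyle exposure derivation and the combined lifestyle risk score.

Four exposures are derived from questionnaire-style raw inputs:

* smoking as pack-years (one pack = 20 cigarettes per day for one year),
* alcohol as grams of pure ethanol per month,
* social integration as a Berkman-style index
  (partnership + close ties + active memberships),
* physical activity as MET-hours per reporting window.

The combined risk score z-transforms each exposure on the fitting cohort,
reverses the sign of the protective behaviours (social integration, physical
activity), and shifts each component so risk components are non-negative
(z - min z) and protective components non-positive ((-z) - max(-z)); the sum
of the four shifted components is the combined score.  Zero marks a
mathematical balance of risk and protection; higher is riskier.  The
transform constants are estimated once on the fitting cohort and reused when
scoring new subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SmokingHistory",
    "BeverageIntake",
    "SocialProfile",
    "ActivityRecord",
    "RiskScorer",
    "RiskScoreResult",
    "compute_pack_years",
    "compute_alcohol_g_month",
    "compute_social_index",
    "compute_met_score",
    "combined_risk_score",
    "ETHANOL_G_PER_L",
    "DEFAULT_ALCOHOL_FRACTIONS",
    "DEFAULT_SERVING_VOLUMES_L",
]

RISK_VARS = ("pack_years", "alcohol_g_month")
PROTECTIVE_VARS = ("social_index", "met_score")
ALL_VARS = RISK_VARS + PROTECTIVE_VARS

#: Density of pure ethanol, grams per litre (convention, configurable).
ETHANOL_G_PER_L = 789.0

#: Conventional alcohol volume fractions per beverage.
DEFAULT_ALCOHOL_FRACTIONS = {
    "beer": 0.048,
    "red_wine": 0.11,
    "white_wine": 0.11,
    "spirits": 0.33,
}

#: Standard serving volumes in litres (beer/wine one 0.2-l glass, spirits 0.02 l).
DEFAULT_SERVING_VOLUMES_L = {
    "beer": 0.2,
    "red_wine": 0.2,
    "white_wine": 0.2,
    "spirits": 0.02,
}


@dataclass(frozen=True)
class SmokingHistory:
    years_smoked: float
    cigarettes_per_day: float

    def __post_init__(self) -> None:
        for name in ("years_smoked", "cigarettes_per_day"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class BeverageIntake:
    beverage: str
    servings_per_month: float
    serving_volume: float | None = None  # litres
    alcohol_fraction: float | None = None  # volume fraction

    def resolved(self) -> tuple[float, float]:
        volume = self.serving_volume
        fraction = self.alcohol_fraction
        if volume is None:
            if self.beverage not in DEFAULT_SERVING_VOLUMES_L:
                raise ValueError(
                    f"unknown beverage {self.beverage!r} without explicit serving_volume"
                )
            volume = DEFAULT_SERVING_VOLUMES_L[self.beverage]
        if fraction is None:
            if self.beverage not in DEFAULT_ALCOHOL_FRACTIONS:
                raise ValueError(
                    f"unknown beverage {self.beverage!r} without explicit alcohol_fraction"
                )
            fraction = DEFAULT_ALCOHOL_FRACTIONS[self.beverage]
        if volume <= 0:
            raise ValueError("serving_volume must be > 0")
        if not 0 < fraction < 1:
            raise ValueError("alcohol_fraction must lie in (0, 1)")
        if self.servings_per_month < 0:
            raise ValueError("servings_per_month must be >= 0")
        return volume, fraction


@dataclass(frozen=True)
class SocialProfile:
    partnered: bool
    n_children: int = 0
    n_close_relatives: int = 0
    n_friends: int = 0
    n_active_memberships: int = 0

    def __post_init__(self) -> None:
        for name in ("n_children", "n_close_relatives", "n_friends",
                     "n_active_memberships"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ActivityRecord:
    met_value: float  # energy multiple of rest
    hours_per_month: float

    def __post_init__(self) -> None:
        if self.met_value < 1:
            raise ValueError("met_value must be >= 1 (rest equals 1 MET)")
        if self.hours_per_month < 0:
            raise ValueError("hours_per_month must be >= 0")


def compute_pack_years(history: SmokingHistory, *, literal: bool = False) -> float:
    """Lifetime smoking exposure in pack-years.

    Standard definition: years smoked x (cigarettes/day / 20).  With
    ``literal=True`` the division by 20 is skipped (years x cigarettes/day),
    provided for comparison with questionnaire conventions that report the
    raw product.
    """
    cpd = history.cigarettes_per_day
    if not literal:
        cpd = cpd / 20.0
    return history.years_smoked * cpd


def compute_alcohol_g_month(
    intakes: list[BeverageIntake], *, ethanol_g_per_l: float = ETHANOL_G_PER_L
) -> float:
    """Total pure-alcohol consumption in grams per month."""
    total = 0.0
    for intake in intakes:
        volume, fraction = intake.resolved()
        total += volume * fraction * ethanol_g_per_l * intake.servings_per_month
    return total


def compute_social_index(profile: SocialProfile) -> int:
    """Berkman-style social integration index.

    Partnership scores 2; close ties contribute the summed counts of
    children, close relatives, and friends; active organizational
    memberships add one point each.  No cap is applied to the close-ties
    sub-score.
    """
    return (
        (2 if profile.partnered else 0)
        + profile.n_children
        + profile.n_close_relatives
        + profile.n_friends
        + profile.n_active_memberships
    )


def compute_met_score(records: list[ActivityRecord]) -> float:
    """Sum of MET value x hours over up to four reported activities."""
    if len(records) > 4:
        raise ValueError("at most 4 activity records per subject are supported")
    return float(sum(r.met_value * r.hours_per_month for r in records))


@dataclass
class RiskScorer:
    """Fitted transform constants of the combined lifestyle risk score.

    For each exposure: ``z = (x - mean) / sd`` on the fitting cohort; risk
    components are ``z - min_z`` (>= 0), protective components are
    ``(-z) - max(-z)`` (<= 0).  ``shift`` stores ``min_z`` for risk
    variables and ``max(-z)`` for protective ones.
    """

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    shift: dict[str, float] = field(default_factory=dict)

    def components(self, exposures: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted transform; does not refit on the new cohort."""
        out = {}
        for name in ALL_VARS:
            if name not in exposures:
                raise KeyError(f"exposure table is missing column {name!r}")
            z = (exposures[name].to_numpy(float) - self.mean[name]) / self.sd[name]
            if name in RISK_VARS:
                out[name] = z - self.shift[name]
            else:
                out[name] = (-z) - self.shift[name]
        return pd.DataFrame(out, index=exposures.index)

    def score(self, exposures: pd.DataFrame) -> pd.Series:
        comp = self.components(exposures)
        return comp.sum(axis=1).rename("risk_score")

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "shift": self.shift}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskScorer":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]), shift=dict(d["shift"]))


@dataclass
class RiskScoreResult:
    """Combined score plus per-variable components and transform constants."""

    score: pd.Series
    components: pd.DataFrame
    scorer: RiskScorer


def combined_risk_score(exposures: pd.DataFrame) -> RiskScoreResult:
    """Fit the combined lifestyle risk score on a cohort.

    Requires >= 2 subjects and positive SD in every exposure (z-scores are
    undefined otherwise).  The returned :class:`RiskScorer` can score new
    subjects with the fitting cohort's constants.
    """
    if len(exposures) < 2:
        raise ValueError("combined risk score needs at least 2 subjects")
    scorer = RiskScorer()
    for name in ALL_VARS:
        if name not in exposures:
            raise KeyError(f"exposure table is missing column {name!r}")
        x = exposures[name].to_numpy(float)
        if np.isnan(x).any():
            raise ValueError(f"exposure {name!r} contains missing values")
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0:
            raise ValueError(f"exposure {name!r} has zero variance")
        scorer.mean[name], scorer.sd[name] = mean, sd
        z = (x - mean) / sd
        scorer.shift[name] = float(z.min()) if name in RISK_VARS else float((-z).max())
    components = scorer.components(exposures)
    return RiskScoreResult(
        score=components.sum(axis=1).rename("risk_score"),
        components=components,
        scorer=scorer,
    )
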