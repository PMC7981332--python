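"""Synthetic cohort generator with known ground-truth lifestyle effects.

Generates phenotype tables (age, sex, education, BMI, DemTect, lifestyle
exposures) together with gray-matter (GM) probability features whose
expectation declines with *effective* brain age (chronological age plus a
latent, lifestyle-driven offset).  Because the lifestyle effect enters the
features only through effective age, a downstream brain-age estimator can
recover it only from the simulated anatomy, which is the causal structure
the analysis pipeline is meant to detect.

Lifestyle exposures are drawn from truncated normals calibrated so that the
*truncated* mean equals the configured mean exactly; see
:func:`calibrate_truncnorm` for why the SD is matched only as closely as the
family allows.
"""

from __future__ import annotations

import dataclasses
import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LifestyleParams",
    "SimulationConfig",
    "GMFeatureMatrix",
    "SyntheticCohort",
    "calibrate_truncnorm",
    "generate_cohort",
    "generate_gm_features",
    "DEFAULT_LIFESTYLE_PARAMS",
    "DEFAULT_EFFECT_MONTHS",
]

LIFESTYLE_VARS = ("pack_years", "alcohol_g_month", "met_score", "social_index")

#: Calibration defaults: (mean, sd, min, max) of each lifestyle exposure in
#: the older population-based cohort the generator emulates.  Units:
#: pack-years; grams of pure ethanol per month; MET-hours per reporting
#: window; social-integration index points.
DEFAULT_LIFESTYLE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "pack_years": (13.61, 21.73, 0.0, 204.0),
    "alcohol_g_month": (11.25, 19.87, 0.0, 198.5),
    "met_score": (14.32, 20.94, 0.0, 196.0),
    "social_index": (12.99, 6.40, 3.0, 53.0),
}

#: Months of brain-age offset per one-unit increase of each exposure
#: (positive = older-looking brain).  Smoking and physical activity carry
#: the effects observed for this population; alcohol and social integration
#: showed none, so their injected effect defaults to zero.
DEFAULT_EFFECT_MONTHS: dict[str, float] = {
    "pack_years": 0.6,
    "alcohol_g_month": 0.0,
    "met_score": -0.55,
    "social_index": 0.0,
}


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class LifestyleParams:
    """Marginal (mean, sd, min, max) of one lifestyle exposure."""

    mean: float
    sd: float
    min: float
    max: float

    def validate(self, name: str) -> None:
        if not np.isfinite([self.mean, self.sd, self.min, self.max]).all():
            raise ConfigError(f"lifestyle_params[{name!r}]: non-finite value")
        if self.sd <= 0:
            raise ConfigError(f"lifestyle_params[{name!r}].sd must be > 0")
        if self.min >= self.max:
            raise ConfigError(f"lifestyle_params[{name!r}]: min must be < max")
        if not (self.min <= self.mean <= self.max):
            raise ConfigError(
                f"lifestyle_params[{name!r}].mean must lie inside [min, max]"
            )


def _default_lifestyle_params() -> dict[str, LifestyleParams]:
    return {k: LifestyleParams(*v) for k, v in DEFAULT_LIFESTYLE_PARAMS.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic cohort.

    Parameters
    ----------
    n_subjects:
        Cohort size.
    seed:
        Seed for all random draws; identical (config, seed) pairs produce
        byte-identical cohorts.
    age_min, age_max:
        Uniform age range in years (adult span by default).
    prop_male:
        Expected fraction of male subjects.
    lifestyle_params:
        Per-exposure truncated-normal marginals.
    lifestyle_corr:
        Optional correlation matrix (order of :data:`LIFESTYLE_VARS`) for a
        Gaussian copula between exposures; identity (independence) when None.
    effect_months:
        Months of latent brain-age offset per unit of each exposure.
    estimator_noise_sd:
        SD (years) of the exposure-independent part of the latent offset.
    n_features:
        Number of GM probability features.
    feature_noise_sd:
        Additive feature noise, GM-probability units.
    age_trend:
        (linear, quadratic) coefficients of mean GM decline per year of
        effective age; both should be <= 0 for a monotone decline.
    """

    n_subjects: int = 1000
    seed: int = 0
    age_min: float = 18.5
    age_max: float = 87.0
    prop_male: float = 0.55
    lifestyle_params: dict[str, LifestyleParams] = field(
        default_factory=_default_lifestyle_params
    )
    lifestyle_corr: np.ndarray | None = None
    effect_months: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MONTHS)
    )
    estimator_noise_sd: float = 3.0
    n_features: int = 64
    feature_noise_sd: float = 0.02
    age_trend: tuple[float, float] = (-0.002, -2e-5)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not self.age_min < self.age_max:
            raise ConfigError("age_min must be < age_max")
        if not 0.0 <= self.prop_male <= 1.0:
            raise ConfigError("prop_male must lie in [0, 1]")
        if self.n_features < 2:
            raise ConfigError("n_features must be >= 2 (PCA undefined below 2)")
        if self.feature_noise_sd < 0:
            raise ConfigError("feature_noise_sd must be >= 0")
        if self.estimator_noise_sd < 0:
            raise ConfigError("estimator_noise_sd must be >= 0")
        for name in LIFESTYLE_VARS:
            if name not in self.lifestyle_params:
                raise ConfigError(f"lifestyle_params missing {name!r}")
            self.lifestyle_params[name].validate(name)
        for name in self.effect_months:
            if name not in LIFESTYLE_VARS:
                raise ConfigError(f"effect_months has unknown variable {name!r}")
        if self.lifestyle_corr is not None:
            R = np.asarray(self.lifestyle_corr, dtype=float)
            if R.shape != (len(LIFESTYLE_VARS), len(LIFESTYLE_VARS)):
                raise ConfigError("lifestyle_corr must be 4x4")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ConfigError("lifestyle_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise ConfigError("lifestyle_corr must be positive semi-definite")


@dataclass
class GMFeatureMatrix:
    """Subjects x features gray-matter probabilities in [0, 1]."""

    values: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x features)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length must match number of rows")
        if self.values.shape[1] < 2:
            raise ValueError("feature matrix needs >= 2 features")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SyntheticCohort:
    """One generated cohort: phenotypes, GM features, and the latent truth."""

    phenotypes: pd.DataFrame
    features: GMFeatureMatrix
    true_offset: np.ndarray
    config_used: SimulationConfig
    clip_rate: float = 0.0


def _truncnorm_moments_std(a: float, b: float) -> tuple[float, float]:
    """Mean and SD of a standard normal truncated to [a, b].

    Uses erfcx-based Mills ratios so the result stays finite deep in the
    tails (plain phi/Phi ratios underflow for |a| beyond ~8).
    """
    from scipy.special import erfcx

    s2 = np.sqrt(2.0)
    # Q(x) = phi(x) * erfcx(x/sqrt(2)) * sqrt(pi/2) ... work with ratios only
    # r(x) = phi(x)/ (Q(a) - Q(b)) computed via exp of log-differences
    def ratio(x: float) -> float:
        # phi(x) / (Q(a) - Q(b)) with Q(t) = 0.5*exp(-t^2/2)*erfcx(t/sqrt(2));
        # everything is expressed relative to Q(a) so no term overflows
        rho = np.exp((a * a - b * b) / 2.0) * erfcx(b / s2) / erfcx(a / s2) \
            if np.isfinite(b) else 0.0
        phi_over_qa = np.exp((a * a - x * x) / 2.0) / (
            0.5 * np.sqrt(2 * np.pi) * erfcx(a / s2)
        )
        return phi_over_qa / (1.0 - rho)

    if a > 0:  # both bounds in the upper tail: stable as-is
        ra, rb = ratio(a), (ratio(b) if np.isfinite(b) else 0.0)
    elif b < 0:  # mirror the lower tail onto the upper one
        m, s = _truncnorm_moments_std(-b, -a)
        return -m, s
    else:
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        ra = stats.norm.pdf(a) / z
        rb = stats.norm.pdf(b) / z
    mean = ra - rb
    a_ra = a * ra if np.isfinite(a) else 0.0
    b_rb = b * rb if np.isfinite(b) else 0.0
    var = 1.0 + a_ra - b_rb - mean**2
    return float(mean), float(np.sqrt(max(var, 0.0)))


@functools.lru_cache(maxsize=256)
def calibrate_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float, float, float]:
    """Find parent (mu, sigma) so the [lo, hi]-truncated normal matches `mean`.

    A normal truncated at a finite lower bound cannot have a coefficient of
    variation above 1 (the exponential limit), so for heavily zero-piled
    exposures such as pack-years the target SD may be unattainable.  The
    calibration therefore matches the truncated mean exactly and chooses the
    parent sigma that brings the truncated SD as close to the target as the
    family allows.

    Returns ``(mu, sigma, achieved_mean, achieved_sd)``.
    """

    def trunc_moments(mu: float, sigma: float) -> tuple[float, float]:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, s = _truncnorm_moments_std(a, b)
        return mu + sigma * m, sigma * s

    def mu_for_mean(sigma: float) -> float:
        # truncated mean is strictly increasing in mu
        def f(mu: float) -> float:
            return trunc_moments(mu, sigma)[0] - mean

        # expand the bracket until it straddles the target mean (needed
        # because for large sigma the truncated mean is insensitive to mu)
        lo_mu, hi_mu = lo - sigma, hi + sigma
        for _ in range(200):
            if f(lo_mu) < 0:
                break
            lo_mu = lo - 2 * (lo - lo_mu + sigma)
        for _ in range(200):
            if f(hi_mu) > 0:
                break
            hi_mu = hi + 2 * (hi_mu - hi + sigma)
        return optimize.brentq(f, lo_mu, hi_mu, xtol=1e-10 * max(1.0, sd))

    def sd_gap(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        mu = mu_for_mean(sigma)
        return abs(trunc_moments(mu, sigma)[1] - sd)

    res = optimize.minimize_scalar(
        sd_gap, bounds=(np.log(sd / 20), np.log(sd * 20)), method="bounded",
        options={"xatol": 1e-6},
    )
    sigma = float(np.exp(res.x))
    mu = mu_for_mean(sigma)
    m, s = trunc_moments(mu, sigma)
    return mu, sigma, m, s


def _seed_streams(seed: int) -> dict[str, np.random.Generator]:
    keys = ("ages", "sex", "lifestyle", "covariates", "offset", "loadings", "noise")
    children = np.random.SeedSequence(seed).spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


def _draw_lifestyle(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_subjects
    # Gaussian copula: standard-normal draws (correlated if requested),
    # pushed through each calibrated truncated-normal marginal.
    if config.lifestyle_corr is None:
        z = rng.standard_normal((n, len(LIFESTYLE_VARS)))
    else:
        L = np.linalg.cholesky(
            np.asarray(config.lifestyle_corr, float)
            + 1e-12 * np.eye(len(LIFESTYLE_VARS))
        )
        z = rng.standard_normal((n, len(LIFESTYLE_VARS))) @ L.T
    u = stats.norm.cdf(z)
    out = {}
    for j, name in enumerate(LIFESTYLE_VARS):
        p = config.lifestyle_params[name]
        mu, sigma, _, _ = calibrate_truncnorm(p.mean, p.sd, p.min, p.max)
        a, b = (p.min - mu) / sigma, (p.max - mu) / sigma
        x = stats.truncnorm.ppf(np.clip(u[:, j], 1e-12, 1 - 1e-12), a, b,
                                loc=mu, scale=sigma)
        out[name] = np.clip(x, p.min, p.max)
    return pd.DataFrame(out)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (phenotypes + GM features).

    Ages are uniform on [age_min, age_max]; sex is Bernoulli(prop_male);
    lifestyle exposures follow calibrated truncated normals; the latent
    brain-age offset (years) is::

        offset_i = sum_v effect_months[v]/12 * (x_iv - mean_v) + N(0, noise^2)

    so that with all effects zero the offset is pure noise.
    """
    config.validate()
    rngs = _seed_streams(config.seed)
    n = config.n_subjects

    ages = rngs["ages"].uniform(config.age_min, config.age_max, size=n)
    male = rngs["sex"].random(n) < config.prop_male
    lifestyle = _draw_lifestyle(config, rngs["lifestyle"])

    cov_rng = rngs["covariates"]
    education = np.clip(np.rint(cov_rng.normal(6.0, 2.0, n)), 1, 10).astype(int)
    bmi = np.clip(cov_rng.normal(27.5, 4.4, n), 16.0, 45.0)
    demtect = np.clip(np.rint(cov_rng.normal(14.8, 2.2, n)), 0, 18).astype(int)

    offset = rngs["offset"].normal(0.0, config.estimator_noise_sd, n)
    for name, months in config.effect_months.items():
        p = config.lifestyle_params[name]
        offset = offset + (months / 12.0) * (lifestyle[name].to_numpy() - p.mean)

    phenotypes = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "age": ages,
            "sex": np.where(male, "male", "female"),
            "education": education,
            "bmi": bmi,
            "demtect": demtect,
        }
    )
    phenotypes = pd.concat([phenotypes, lifestyle], axis=1)

    cohort = SyntheticCohort(
        phenotypes=phenotypes,
        features=None,  # type: ignore[arg-type]  # filled just below
        true_offset=offset,
        config_used=config,
    )
    cohort.features = generate_gm_features(cohort, config)
    return cohort


def generate_gm_features(
    cohort: SyntheticCohort, config: SimulationConfig
) -> GMFeatureMatrix:
    """Simulate GM probability features from effective brain age.

    ``feature_ij = clip_[0,1]( base_j + L_j * g(age_i + offset_i) + eps_ij )``
    where ``g(a) = c1*a + c2*a^2`` (configured ``age_trend``) and the
    per-feature loadings ``L_j`` and baselines ``base_j`` are fixed by the
    config seed, so regenerating features for the same cohort/config is
    deterministic.
    """
    if config.n_features < 2:
        raise ConfigError("n_features must be >= 2 (PCA undefined below 2)")
    rngs = _seed_streams(config.seed)
    load_rng, noise_rng = rngs["loadings"], rngs["noise"]

    p = config.n_features
    base = load_rng.uniform(0.65, 0.85, p)
    loadings = load_rng.uniform(0.6, 1.4, p)
    c1, c2 = config.age_trend

    eff_age = cohort.phenotypes["age"].to_numpy() + cohort.true_offset
    g = c1 * eff_age + c2 * eff_age**2
    raw = base[None, :] + loadings[None, :] * g[:, None]
    if config.feature_noise_sd > 0:
        raw = raw + noise_rng.normal(0.0, config.feature_noise_sd, raw.shape)
    clipped = np.clip(raw, 0.0, 1.0)
    cohort.clip_rate = float(np.mean(raw != clipped))
    return GMFeatureMatrix(values=clipped,
                           subject_ids=cohort.phenotypes["subject_id"].to_numpy())


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config (for YAML/JSON serialization)."""
    d = dataclasses.asdict(config)
    d["lifestyle_params"] = {
        k: dataclasses.asdict(v) for k, v in config.lifestyle_params.items()
    }
    if config.lifestyle_corr is not None:
        d["lifestyle_corr"] = np.asarray(config.lifestyle_corr).tolist()
    d["age_trend"] = list(config.age_trend)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "lifestyle_params" in d:
        d["lifestyle_params"] = {
            k: LifestyleParams(**v) if isinstance(v, dict) else LifestyleParams(*v)
            for k, v in d["lifestyle_params"].items()
        }
    if d.get("lifestyle_corr") is not None:
        d["lifestyle_corr"] = np.asarray(d["lifestyle_corr"], float)
    if "age_trend" in d:
        d["age_trend"] = tuple(d["age_trend"])
    return SimulationConfig(**d)
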