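"""Statistical layer linking lifestyle to the brain-age gap.

Implements the three ways of handling chronological age in models of the
brain-age gap (BrainAGE):

* approach 1 — age enters the regression as a predictor,
* approach 2 — age is omitted,
* approach 3 — age is regressed out of BrainAGE first and the residual is
  the outcome.

plus the surrounding inference machinery: 3-SD outlier masking, sex x
lifestyle interaction ANCOVA, sex-stratified refits, linear-vs-quadratic
curve comparison on residualized exposures, the never/moderate/severe
smoker contrast with age matching, noncentral-F power for the applied
regression models, month-scale effect quantification, and descriptive
correlation tables.  Ordinary model fits go through statsmodels OLS; sums
of squares for factor effects are computed by nested model comparison.

Sex is coded female = 0, male = 1 throughout (F-tests are invariant to the
coding; coefficient signs are documented relative to it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "TermResult",
    "InteractionTest",
    "CurveFitComparison",
    "PowerRequest",
    "PowerResult",
    "SmokerGroupResult",
    "exclude_outliers",
    "fit_lifestyle_model",
    "quantify_months",
    "test_sex_interaction",
    "compare_linear_quadratic",
    "smoker_group_analysis",
    "compute_power",
    "bonferroni_alpha",
    "descriptives",
    "sex_to_numeric",
]

DEFAULT_FAMILY_SIZE = 15  # 5 lifestyle terms x (pooled, male, female) analyses


def sex_to_numeric(sex: pd.Series | np.ndarray) -> np.ndarray:
    """Code sex as female = 0, male = 1 (accepts strings or 0/1)."""
    s = pd.Series(sex)
    if s.dtype.kind in "biufc":
        return s.to_numpy(float)
    mapping = {"female": 0.0, "f": 0.0, "male": 1.0, "m": 1.0}
    out = s.astype(str).str.lower().map(mapping)
    if out.isna().any():
        bad = sorted(set(s[out.isna()].astype(str)))
        raise ValueError(f"unrecognized sex labels: {bad}")
    return out.to_numpy(float)


def bonferroni_alpha(alpha: float = 0.05, family_size: int = DEFAULT_FAMILY_SIZE) -> float:
    """Per-test threshold for a Bonferroni-corrected family of tests."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size


def exclude_outliers(values: np.ndarray) -> np.ndarray:
    """Inclusion mask: keep values deviating less than 3 SD from the mean.

    Mean and SD (population form) are computed once on the full vector (no
    iteration); a value exactly at the 3-SD boundary counts as an outlier.
    With zero SD every value is included and a warning is emitted.
    """
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ValueError("outlier exclusion needs at least 3 values")
    sd = np.std(x)
    if sd == 0:
        warnings.warn("zero variance; no outliers excluded", RuntimeWarning,
                      stacklevel=2)
        return np.ones(len(x), dtype=bool)
    return np.abs(x - np.mean(x)) < 3.0 * sd


# ---------------------------------------------------------------------------
# Lifestyle -> BrainAGE regressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One lifestyle -> BrainAGE regression specification.

    Approach 1 forces chronological age into the covariates; approaches 2
    and 3 never use age as a predictor (approach 3 residualizes the outcome
    on age instead).
    """

    approach: int = 1
    lifestyle_terms: tuple[str, ...] = ("risk_score",)
    covariates: tuple[str, ...] = ("sex",)
    stratum: str = "all"  # all | male | female
    outlier_rule: str = "off"  # off | 3SD
    outcome: str = "brainage"

    def __post_init__(self) -> None:
        if self.approach not in (1, 2, 3):
            raise ValueError("approach must be 1, 2 or 3")
        if self.stratum not in ("all", "male", "female"):
            raise ValueError("stratum must be all, male or female")
        if self.outlier_rule not in ("off", "3SD"):
            raise ValueError("outlier_rule must be 'off' or '3SD'")

    def effective_covariates(self) -> tuple[str, ...]:
        cov = [c for c in self.covariates if c != "age"]
        if self.stratum != "all":
            cov = [c for c in cov if c != "sex"]
        if self.approach == 1:
            cov = ["age"] + cov
        return tuple(dict.fromkeys(cov))


@dataclass
class TermResult:
    term: str
    b: float
    beta: float
    t: float
    p: float
    se: float


@dataclass
class RegressionFit:
    """One fitted lifestyle -> BrainAGE model."""

    spec: ModelSpec
    n: int
    terms: dict[str, TermResult]
    intercept: float
    f_value: float
    f_p: float
    r2: float
    delta_r2: float  # R^2 attributable to the lifestyle term(s)
    residual_mae: float
    residual_sd: float

    def lifestyle(self, name: str | None = None) -> TermResult:
        name = name or self.spec.lifestyle_terms[0]
        return self.terms[name]


def _prepare_frame(data: pd.DataFrame, columns: list[str], stratum: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise KeyError(f"data is missing columns {missing}")
    df = data.copy()
    df["sex"] = sex_to_numeric(df["sex"]) if "sex" in df else np.nan
    if stratum == "male":
        df = df[df["sex"] == 1.0]
    elif stratum == "female":
        df = df[df["sex"] == 0.0]
    df = df.dropna(subset=columns)  # listwise deletion
    return df


def _check_collinear(X: pd.DataFrame) -> None:
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols: list[int] = []
        for j, name in enumerate(X.columns):
            trial = cols + [j]
            if np.linalg.matrix_rank(mat[:, trial]) == len(cols):
                bad.append(name)
            else:
                cols.append(j)
        raise ValueError(f"perfectly collinear terms in design: {bad}")


def fit_lifestyle_model(data: pd.DataFrame, spec: ModelSpec) -> RegressionFit:
    """OLS of BrainAGE on lifestyle term(s) plus covariates.

    Approach 3 first replaces the outcome by the residuals of
    ``outcome ~ 1 + age`` computed on the analysis sample.  ``delta_r2`` is
    R^2(full) - R^2(covariates only) on the same rows; ``residual_mae`` is
    the mean absolute OLS residual.
    """
    lifestyle = list(spec.lifestyle_terms)
    covars = list(spec.effective_covariates())
    needed = [spec.outcome, "age", "sex"] + lifestyle + [c for c in covars
                                                         if c not in ("age", "sex")]
    df = _prepare_frame(data, list(dict.fromkeys(needed)), spec.stratum)
    if spec.outlier_rule == "3SD":
        mask = np.ones(len(df), dtype=bool)
        for term in lifestyle:
            mask &= exclude_outliers(df[term].to_numpy())
        df = df[mask]
    n = len(df)
    if n <= len(lifestyle) + len(covars) + 1:
        raise ValueError(f"too few rows (n={n}) for the requested model")

    y = df[spec.outcome].to_numpy(float)
    if spec.approach == 3:
        age_design = sm.add_constant(df["age"].to_numpy(float))
        y = sm.OLS(y, age_design).fit().resid

    X_full = df[covars + lifestyle].astype(float)
    _check_collinear(sm.add_constant(X_full))
    full = sm.OLS(y, sm.add_constant(X_full)).fit()
    if covars:
        reduced = sm.OLS(y, sm.add_constant(df[covars].astype(float))).fit()
        delta_r2 = float(full.rsquared - reduced.rsquared)
    else:
        delta_r2 = float(full.rsquared)

    sd_y = np.std(y, ddof=1)
    terms = {}
    for name in covars + lifestyle:
        b = float(full.params[name])
        beta = b * np.std(df[name].to_numpy(float), ddof=1) / sd_y if sd_y > 0 else np.nan
        terms[name] = TermResult(
            term=name, b=b, beta=float(beta), t=float(full.tvalues[name]),
            p=float(full.pvalues[name]), se=float(full.bse[name]),
        )
    resid = full.resid
    return RegressionFit(
        spec=spec, n=n, terms=terms,
        intercept=float(full.params["const"]),
        f_value=float(full.fvalue), f_p=float(full.f_pvalue),
        r2=float(full.rsquared), delta_r2=delta_r2,
        residual_mae=float(np.mean(np.abs(resid))),
        residual_sd=float(np.std(resid, ddof=1)),
    )


def quantify_months(b3: float) -> float:
    """Convert a BrainAGE slope (years per exposure unit) to months per unit."""
    if not np.isfinite(b3):
        raise ValueError("coefficient must be finite")
    return b3 * 12.0


# ---------------------------------------------------------------------------
# Interaction and curve comparison
# ---------------------------------------------------------------------------

@dataclass
class InteractionTest:
    term: str
    f_value: float
    p: float
    partial_eta_sq: float
    df_num: int
    df_den: int


def test_sex_interaction(
    data: pd.DataFrame,
    lifestyle_terms: tuple[str, ...] | list[str],
    covariates: tuple[str, ...] = ("age", "education"),
    outcome: str = "brainage",
) -> dict[str, InteractionTest]:
    """ANCOVA with sex x lifestyle interaction term(s).

    Fits OLS with main effects (sex, covariates, lifestyle terms) plus one
    product term per lifestyle variable, and tests each product term by
    nested model comparison (equivalently a partial F test).  Partial eta^2
    is SS_effect / (SS_effect + SS_error).
    """
    lifestyle = list(lifestyle_terms)
    cols = [outcome, "sex"] + list(covariates) + lifestyle
    df = _prepare_frame(data, list(dict.fromkeys(cols)), "all")
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present for an interaction test")
    y = df[outcome].to_numpy(float)
    X = df[["sex"] + list(covariates) + lifestyle].astype(float).copy()
    for term in lifestyle:
        X[f"sex:{term}"] = X["sex"] * X[term]
    full = sm.OLS(y, sm.add_constant(X)).fit()
    out = {}
    for term in lifestyle:
        reduced_cols = [c for c in X.columns if c != f"sex:{term}"]
        reduced = sm.OLS(y, sm.add_constant(X[reduced_cols])).fit()
        ss_effect = float(reduced.ssr - full.ssr)
        df_num = 1
        df_den = int(full.df_resid)
        f_value = (ss_effect / df_num) / (full.ssr / df_den)
        p = float(stats.f.sf(f_value, df_num, df_den))
        out[term] = InteractionTest(
            term=term, f_value=float(f_value), p=p,
            partial_eta_sq=float(ss_effect / (ss_effect + full.ssr)),
            df_num=df_num, df_den=df_den,
        )
    return out


@dataclass
class CurveFitComparison:
    r2_linear: float
    r2_quadratic: float
    b1_linear: float
    b1_quadratic: float
    b2_quadratic: float
    p_quadratic: float


def compare_linear_quadratic(
    data: pd.DataFrame,
    lifestyle_term: str,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    outcome: str = "brainage",
) -> CurveFitComparison:
    """Linear vs quadratic fit of BrainAGE on a residualized exposure.

    The exposure is first residualized on the covariates (with intercept);
    BrainAGE is then regressed on the residual, and on the residual plus its
    square.  R^2(quadratic) >= R^2(linear) by nesting.
    """
    cols = [outcome, lifestyle_term] + list(covariates)
    df = _prepare_frame(data, list(dict.fromkeys(cols)), "all")
    if len(df) < 5:
        raise ValueError("curve comparison needs at least 5 subjects")
    y = df[outcome].to_numpy(float)
    C = sm.add_constant(df[list(covariates)].astype(float))
    x = sm.OLS(df[lifestyle_term].to_numpy(float), C).fit().resid

    lin = sm.OLS(y, sm.add_constant(pd.DataFrame({"x": x}))).fit()
    quad = sm.OLS(y, sm.add_constant(pd.DataFrame({"x": x, "x2": x**2}))).fit()
    return CurveFitComparison(
        r2_linear=float(lin.rsquared),
        r2_quadratic=float(quad.rsquared),
        b1_linear=float(lin.params["x"]),
        b1_quadratic=float(quad.params["x"]),
        b2_quadratic=float(quad.params["x2"]),
        p_quadratic=float(quad.pvalues["x2"]),
    )


# ---------------------------------------------------------------------------
# Smoker groups
# ---------------------------------------------------------------------------

@dataclass
class SmokerGroupResult:
    groups: pd.Series  # label per (input) subject: never | moderate | severe
    matched_ids: list
    adjusted_means: dict[str, float]
    f_value: float
    p: float
    df_num: int
    df_den: int
    pairwise: dict[str, tuple[float, float]]  # contrast -> (difference, p)
    group_counts: dict[str, int]


def classify_smokers(pack_years: np.ndarray) -> np.ndarray:
    """never (0), moderate (0 < py < 20), severe (py >= 20)."""
    py = np.asarray(pack_years, float)
    out = np.where(py == 0, "never", np.where(py < 20, "moderate", "severe"))
    return out


def _match_groups(
    df: pd.DataFrame, caliper: float, seed: int
) -> list:
    """Age-match the three smoker groups within sex.

    Nearest-neighbour matching without replacement on age, caliper in
    years; reference group is the smallest; ties broken by subject id after
    a seeded shuffle of the reference order.
    """
    rng = np.random.default_rng(seed)
    matched: list = []
    for _, sub in df.groupby("sex"):
        pools = {g: sub[sub["group"] == g].sort_values("subject_id").copy()
                 for g in ("never", "moderate", "severe")}
        if any(len(p) == 0 for p in pools.values()):
            continue
        ref_name = min(pools, key=lambda g: len(pools[g]))
        ref = pools[ref_name]
        order = ref.index.to_numpy()[rng.permutation(len(ref))]
        used = {g: np.zeros(len(pools[g]), dtype=bool) for g in pools}
        for i in order:
            age_i = ref.loc[i, "age"]
            picks = {ref_name: i}
            ok = True
            for g, pool in pools.items():
                if g == ref_name:
                    continue
                diffs = np.abs(pool["age"].to_numpy() - age_i)
                diffs[used[g]] = np.inf
                j = int(np.argmin(diffs))  # ties -> lowest subject id (sorted)
                if diffs[j] > caliper:
                    ok = False
                    break
                picks[g] = pool.index[j]
            if ok:
                for g, ix in picks.items():
                    if g != ref_name:
                        used[g][pools[g].index.get_loc(ix)] = True
                    matched.append(ix)
    return matched


def smoker_group_analysis(
    data: pd.DataFrame,
    *,
    caliper: float = 2.0,
    seed: int = 0,
    outcome: str = "brainage",
) -> SmokerGroupResult:
    """Never/moderate/severe smoker contrast on age-matched groups.

    Groups are classified from pack-years at the printed thresholds,
    age-matched within sex (nearest neighbour, no replacement), and
    compared by ANCOVA: OLS of BrainAGE on group indicators, sex, age and
    education, with the group effect tested by nested model comparison.
    Adjusted means are predictions at the matched sample's covariate means.
    """
    cols = [outcome, "pack_years", "age", "sex", "education", "subject_id"]
    df = _prepare_frame(data, [c for c in cols if c != "subject_id"], "all")
    if "subject_id" not in df:
        df = df.assign(subject_id=np.arange(len(df)))
    df = df.assign(group=classify_smokers(df["pack_years"].to_numpy()))
    counts = df["group"].value_counts().to_dict()
    for g in ("never", "moderate", "severe"):
        if counts.get(g, 0) == 0:
            raise ValueError(f"smoker group {g!r} is empty; group counts: {counts}")

    matched_index = _match_groups(df, caliper, seed)
    m = df.loc[matched_index]
    if m["group"].nunique() < 3:
        raise ValueError("age matching produced fewer than 3 groups; widen caliper")

    y = m[outcome].to_numpy(float)
    d_mod = (m["group"] == "moderate").astype(float)
    d_sev = (m["group"] == "severe").astype(float)
    X = pd.DataFrame({
        "moderate": d_mod.to_numpy(),
        "severe": d_sev.to_numpy(),
        "sex": m["sex"].to_numpy(float),
        "age": m["age"].to_numpy(float),
        "education": m["education"].to_numpy(float),
    })
    full = sm.OLS(y, sm.add_constant(X)).fit()
    reduced = sm.OLS(y, sm.add_constant(X[["sex", "age", "education"]])).fit()
    df_num, df_den = 2, int(full.df_resid)
    f_value = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(stats.f.sf(f_value, df_num, df_den))

    base = {
        "sex": float(X["sex"].mean()),
        "age": float(X["age"].mean()),
        "education": float(X["education"].mean()),
    }
    c = full.params
    ref_mean = c["const"] + sum(c[k] * v for k, v in base.items())
    adjusted = {
        "never": float(ref_mean),
        "moderate": float(ref_mean + c["moderate"]),
        "severe": float(ref_mean + c["severe"]),
    }
    t_ms = (c["severe"] - c["moderate"]) / np.sqrt(
        full.cov_params().loc["severe", "severe"]
        + full.cov_params().loc["moderate", "moderate"]
        - 2 * full.cov_params().loc["severe", "moderate"]
    )
    pairwise = {
        "moderate-never": (float(c["moderate"]), float(full.pvalues["moderate"])),
        "severe-never": (float(c["severe"]), float(full.pvalues["severe"])),
        "severe-moderate": (
            float(c["severe"] - c["moderate"]),
            float(2 * stats.t.sf(abs(t_ms), df_den)),
        ),
    }
    return SmokerGroupResult(
        groups=pd.Series(df["group"].to_numpy(), index=df.index, name="smoker_group"),
        matched_ids=m["subject_id"].tolist(),
        adjusted_means=adjusted,
        f_value=float(f_value), p=p, df_num=df_num, df_den=df_den,
        pairwise=pairwise,
        group_counts={g: int((m["group"] == g).sum())
                      for g in ("never", "moderate", "severe")},
    )


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerRequest:
    """Noncentral-F power request for a fixed-model multiple regression.

    ``f2`` is Cohen's effect size R^2/(1-R^2) of the tested term(s);
    ``total_predictors`` is the number of predictors p in the full model;
    ``tested_df`` the numerator degrees of freedom (1 for a single tested
    coefficient, p for the deviation-from-zero test of the whole model).
    """

    f2: float
    n: int
    alpha: float = 0.05
    total_predictors: int = 1
    tested_df: int = 1

    def __post_init__(self) -> None:
        if self.f2 < 0:
            raise ValueError("f2 must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n <= self.total_predictors + 1:
            raise ValueError("n must exceed total_predictors + 1")
        if not 1 <= self.tested_df <= self.total_predictors:
            raise ValueError("tested_df must lie in [1, total_predictors]")


@dataclass
class PowerResult:
    power: float
    noncentrality: float
    critical_f: float
    df_num: int
    df_den: int


def compute_power(request: PowerRequest) -> PowerResult:
    """Power of the partial F test with noncentrality lambda = f^2 * n."""
    lam = request.f2 * request.n
    df_num = request.tested_df
    df_den = request.n - request.total_predictors - 1
    fcrit = float(stats.f.isf(request.alpha, df_num, df_den))
    if lam == 0:
        power = request.alpha  # central F: power equals the test level
    else:
        power = float(stats.ncf.sf(fcrit, df_num, df_den, lam))
    return PowerResult(power=power, noncentrality=float(lam), critical_f=fcrit,
                       df_num=df_num, df_den=df_den)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def descriptives(
    data: pd.DataFrame, columns: list[str] | None = None,
    by: str | None = "sex",
) -> dict:
    """Summary statistics plus Pearson and Spearman correlation matrices.

    Correlations involving a zero-variance column are reported as NaN and
    flagged in ``undefined``.  Spearman uses average ranks (tie-corrected).
    """
    if columns is None:
        columns = [c for c in data.columns
                   if pd.api.types.is_numeric_dtype(data[c])]
    df = data[columns].astype(float).dropna()
    summary = {"all": df.describe().loc[["mean", "std", "min", "max"]]}
    if by is not None and by in data.columns:
        for level, sub in data.dropna(subset=columns).groupby(by):
            summary[str(level)] = (
                sub[columns].astype(float)
                .describe().loc[["mean", "std", "min", "max"]]
            )

    k = len(columns)
    pear = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    pear_p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    spear = pear.copy()
    spear_p = pear_p.copy()
    undefined: list[tuple[str, str]] = []
    for i, a in enumerate(columns):
        for j, b in enumerate(columns):
            if j <= i:
                continue
            x, y = df[a].to_numpy(), df[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                pear.loc[a, b] = pear.loc[b, a] = np.nan
                spear.loc[a, b] = spear.loc[b, a] = np.nan
                pear_p.loc[a, b] = pear_p.loc[b, a] = np.nan
                spear_p.loc[a, b] = spear_p.loc[b, a] = np.nan
                undefined.append((a, b))
                continue
            r, rp = stats.pearsonr(x, y)
            rho, rhop = stats.spearmanr(x, y)
            pear.loc[a, b] = pear.loc[b, a] = r
            pear_p.loc[a, b] = pear_p.loc[b, a] = rp
            spear.loc[a, b] = spear.loc[b, a] = rho
            spear_p.loc[a, b] = spear_p.loc[b, a] = rhop
    return {
        "summary": summary,
        "pearson": pear, "pearson_p": pear_p,
        "spearman": spear, "spearman_p": spear_p,
        "undefined": undefined,
        "n": len(df),
    }
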