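"""Pipeline orchestration: simulate -> score -> estimate -> analyze -> report.

File conventions: phenotypes and per-subject results as comma-separated
UTF-8 CSV with a header row and '.' decimals; feature matrices as HDF5
(datasets ``gm_features`` and ``subject_ids``) or CSV for small cohorts;
reports and fitted transform constants as JSON; configuration as YAML.
Every written report embeds a provenance block (config hash, seed, package
version) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brainage import (
    BrainAgeResult,
    CrossValPlan,
    PerformanceReport,
    compute_brainage,
    detrend_quadratic,
    leave_k_out_estimate,
    performance_report,
)
from .inference import (
    DEFAULT_FAMILY_SIZE,
    ModelSpec,
    PowerRequest,
    RegressionFit,
    bonferroni_alpha,
    compute_power,
    fit_lifestyle_model,
    quantify_months,
)
from .lifestyle import ALL_VARS, combined_risk_score
from .synthdata import (
    GMFeatureMatrix,
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
    "load_cohort",
    "write_phenotypes",
    "write_features",
    "load_config",
    "save_config",
]

log = logging.getLogger("brainagekit")

LIFESTYLE_ANALYSIS_VARS = ("risk_score",) + ALL_VARS
REQUIRED_PHENOTYPES = ("subject_id", "age", "sex")


@dataclass
class PipelineConfig:
    """Reproducible configuration of one full pipeline run."""

    output_dir: str = "brainagekit_out"
    phenotypes_path: str | None = None
    features_path: str | None = None
    simulate: SimulationConfig | None = None
    # brain-age settings
    k: int = 10
    sex_split: bool = True
    kernel: str = "linear"
    rbf_width: float | None = None
    variance_target: float = 0.95
    n_components: int | None = None
    seed: int = 0
    # analysis settings
    approaches: tuple[int, ...] = (1, 2, 3)
    covariates: tuple[str, ...] = ("sex",)
    alpha: float = 0.05
    family_size: int = DEFAULT_FAMILY_SIZE
    outlier_rule: str = "off"
    strata: tuple[str, ...] = ("all", "male", "female")
    power_f2: tuple[float, ...] = (0.05, 0.04, 0.07)
    verbosity: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if self.simulate is None:
            for name in ("phenotypes_path", "features_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file: {p}")

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = config_to_dict(self.simulate)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything one pipeline run produces, in memory."""

    phenotypes: pd.DataFrame
    brainage: BrainAgeResult
    plan: CrossValPlan
    performance: PerformanceReport
    regressions: list[RegressionFit]
    regression_table: pd.DataFrame
    power_table: pd.DataFrame
    provenance: dict
    significant_after_bonferroni: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def write_features(features: GMFeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("gm_features", data=features.values, dtype="float64")
            f.create_dataset("subject_ids",
                             data=np.asarray(features.subject_ids, dtype="int64"))
    else:
        df = pd.DataFrame(features.values,
                          columns=[f"f{j}" for j in range(features.n_features)])
        df.insert(0, "subject_id", features.subject_ids)
        df.to_csv(path, index=False, encoding="utf-8")


def _read_features(path: Path) -> GMFeatureMatrix:
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = f["gm_features"][...]
            ids = f["subject_ids"][...] if "subject_ids" in f \
                else np.arange(1, values.shape[0] + 1)
        return GMFeatureMatrix(values=values, subject_ids=ids)
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"feature CSV {path} lacks a subject_id column")
    ids = df["subject_id"].to_numpy()
    vals = df.drop(columns=["subject_id"]).to_numpy(float)
    return GMFeatureMatrix(values=vals, subject_ids=ids)


def load_cohort(
    phenotypes_path: str | Path, features_path: str | Path
) -> tuple[pd.DataFrame, GMFeatureMatrix]:
    """Load and align a phenotype table and a feature matrix by subject id.

    Rows of both structures are sorted by subject id; ids present in only
    one file raise an error listing the orphans.  Phenotype rows missing a
    required field (subject_id, age, sex) are dropped with a logged count.
    """
    phenotypes_path, features_path = Path(phenotypes_path), Path(features_path)
    for p in (phenotypes_path, features_path):
        if not p.exists():
            raise FileNotFoundError(f"no such file: {p}")
    pheno = pd.read_csv(phenotypes_path)
    missing_cols = [c for c in REQUIRED_PHENOTYPES if c not in pheno.columns]
    if missing_cols:
        raise ValueError(f"phenotype file lacks required columns {missing_cols}")
    for col in ("age",):
        bad = pd.to_numeric(pheno[col], errors="coerce").isna() & pheno[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value in column {col!r} at row {row} "
                f"of {phenotypes_path}"
            )
    n0 = len(pheno)
    pheno = pheno.dropna(subset=list(REQUIRED_PHENOTYPES))
    if len(pheno) < n0:
        log.info("excluded %d phenotype rows with missing required fields",
                 n0 - len(pheno))

    feats = _read_features(features_path)
    pheno_ids = set(pheno["subject_id"].tolist())
    feat_ids = set(np.asarray(feats.subject_ids).tolist())
    only_p = sorted(pheno_ids - feat_ids)
    only_f = sorted(feat_ids - pheno_ids)
    if only_p or only_f:
        raise ValueError(
            "subject id mismatch between phenotypes and features; "
            f"only in phenotypes: {only_p[:10]}, only in features: {only_f[:10]}"
        )
    pheno = pheno.sort_values("subject_id").reset_index(drop=True)
    order = np.argsort(np.asarray(feats.subject_ids))
    feats = GMFeatureMatrix(values=feats.values[order],
                            subject_ids=np.asarray(feats.subject_ids)[order])
    return pheno, feats


def save_config(config: PipelineConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    if config.simulate is not None:
        d["simulate"] = config_to_dict(config.simulate)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if d.get("simulate") is not None:
        d["simulate"] = config_from_dict(d["simulate"])
    for key in ("approaches", "covariates", "strata", "power_f2"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PipelineConfig(**d)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def regression_rows(fits: list[RegressionFit]) -> pd.DataFrame:
    """Tidy one-row-per-term table of the fitted lifestyle models."""
    rows = []
    for fit in fits:
        for term in fit.spec.lifestyle_terms:
            tr = fit.terms[term]
            rows.append({
                "term": term,
                "approach": fit.spec.approach,
                "stratum": fit.spec.stratum,
                "covariates": "+".join(fit.spec.effective_covariates()),
                "b": tr.b, "beta": tr.beta, "t": tr.t, "p": tr.p,
                "F": fit.f_value, "R2": fit.r2, "delta_R2": fit.delta_r2,
                "mae": fit.residual_mae, "n": fit.n,
                "months_per_unit": quantify_months(tr.b),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis and write all outputs to ``config.output_dir``.

    Stages: (1) simulate or load the cohort; (2) fit the combined lifestyle
    risk score; (3) sex-split leave-k-out brain-age estimation; (4) raw gap
    + quadratic age detrend + performance report; (5) lifestyle regressions
    for every (term, approach, stratum) combination with Bonferroni
    flagging; (6) noncentral-F power table.  Deterministic given
    (config, seed).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    @_stage("simulate")
    def stage_simulate():
        if config.simulate is not None:
            cohort = generate_cohort(config.simulate)
            return cohort.phenotypes, cohort.features
        return load_cohort(config.phenotypes_path, config.features_path)

    pheno, feats = stage_simulate()
    log.info("cohort: n=%d, %d features", len(pheno), feats.n_features)

    @_stage("score")
    def stage_score():
        result = combined_risk_score(pheno[list(ALL_VARS)])
        return result

    risk = stage_score()
    pheno = pheno.assign(risk_score=risk.score.to_numpy())

    @_stage("estimate")
    def stage_estimate():
        return leave_k_out_estimate(
            pheno, feats, k=config.k, sex_split=config.sex_split,
            seed=config.seed, variance_target=config.variance_target,
            n_components=config.n_components, kernel=config.kernel,
            rbf_width=config.rbf_width,
        )

    estimated, plan = stage_estimate()

    @_stage("detrend")
    def stage_detrend():
        ages = pheno["age"].to_numpy(float)
        raw = compute_brainage(estimated, ages)
        detrended, coef = detrend_quadratic(raw, ages)
        return BrainAgeResult(estimated_age=estimated, raw_gap=raw,
                              brainage=detrended, detrend_coefficients=coef)

    ba = stage_detrend()
    pheno = pheno.assign(estimated_age=ba.estimated_age,
                         raw_gap=ba.raw_gap, brainage=ba.brainage)
    perf = performance_report(
        pheno["age"].to_numpy(float), ba.estimated_age, ba.brainage,
        strata=pheno["sex"].to_numpy(),
    )

    @_stage("analyze")
    def stage_analyze():
        fits = []
        for term in LIFESTYLE_ANALYSIS_VARS:
            for approach in config.approaches:
                for stratum in config.strata:
                    spec = ModelSpec(
                        approach=approach, lifestyle_terms=(term,),
                        covariates=config.covariates, stratum=stratum,
                        outlier_rule=config.outlier_rule,
                    )
                    fits.append(fit_lifestyle_model(pheno, spec))
        return fits

    fits = stage_analyze()
    table = regression_rows(fits)
    threshold = bonferroni_alpha(config.alpha, config.family_size)
    table["significant_bonferroni"] = table["p"] < threshold
    significant = sorted(set(table.loc[table["significant_bonferroni"], "term"]))

    @_stage("power")
    def stage_power():
        rows = []
        for f2 in config.power_f2:
            req = PowerRequest(f2=f2, n=len(pheno), alpha=threshold,
                               total_predictors=5, tested_df=1)
            res = compute_power(req)
            rows.append({"f2": f2, "n": req.n, "alpha": threshold,
                         "power": res.power, "noncentrality": res.noncentrality,
                         "critical_F": res.critical_f})
        return pd.DataFrame(rows)

    power_table = stage_power()

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_subjects": int(len(pheno)),
        "bonferroni_threshold": threshold,
    }

    @_stage("report")
    def stage_report():
        write_phenotypes(
            pheno[["subject_id", "age", "sex", "estimated_age",
                   "raw_gap", "brainage"]],
            outdir / "brainage_per_subject.csv",
        )
        write_phenotypes(pheno, outdir / "phenotypes_scored.csv")
        table.to_csv(outdir / "regression_results.csv", index=False)
        power_table.to_csv(outdir / "power_table.csv", index=False)
        report = {
            "provenance": provenance,
            "performance": perf.to_dict(),
            "risk_score_constants": risk.scorer.to_dict(),
            "detrend_coefficients": ba.detrend_coefficients.tolist(),
            "significant_after_bonferroni": significant,
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
        )
        save_config(config, outdir / "config_used.yaml")

    stage_report()

    return ReportBundle(
        phenotypes=pheno, brainage=ba, plan=plan, performance=perf,
        regressions=fits, regression_table=table, power_table=power_table,
        provenance=provenance, significant_after_bonferroni=significant,
    )
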