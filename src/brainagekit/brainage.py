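"""Brain-age estimation: PCA reduction, relevance vector regression (RVR),
sex-split leave-k-out cross-validation, gap formation and quadratic
age-detrending.

The estimator follows the sparse Bayesian regression of Tipping's relevance
vector machine: weights carry independent zero-mean Gaussian priors with
per-weight precisions ``alpha_i``, the noise precision is ``beta``, and both
are chosen by iterative maximization of the marginal likelihood (evidence),
pruning basis functions whose precision diverges.  For the linear kernel the
model is fit in the primal basis ``[1, X]`` — the linear kernel spans
exactly the space of affine functions, so this is the same model at a far
lower cost than the n x n kernel expansion; the RBF kernel uses the full
relevance-vector expansion over training points.

The brain-age gap is ``estimated - chronological`` age; a least-squares
quadratic age trend (intercept + age + age^2) is removed from the gaps over
the full estimation sample, which makes the detrended gap exactly orthogonal
to {1, age, age^2} and zero-mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA as _SkPCA

from .synthdata import GMFeatureMatrix

__all__ = [
    "PCAModel",
    "RVRModel",
    "CrossValPlan",
    "BrainAgeResult",
    "PerformanceReport",
    "fit_pca",
    "project",
    "sparse_bayes_fit",
    "rvr_log_evidence",
    "fit_rvr",
    "predict_rvr",
    "load_nifti_features",
    "leave_k_out_estimate",
    "compute_brainage",
    "detrend_quadratic",
    "performance_report",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Fitted linear dimensionality reduction (orthonormal loadings)."""

    mean_: np.ndarray
    components_: np.ndarray  # (k, n_features)
    explained_variance_ratio_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]


def _as_matrix(features: GMFeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, GMFeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def fit_pca(
    features: GMFeatureMatrix | np.ndarray,
    variance_target: float | None = 0.95,
    k: int | None = None,
) -> PCAModel:
    """Fit PCA, retaining either `k` components or enough to explain
    `variance_target` of the variance (capped at the data rank)."""
    X = _as_matrix(features)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")
    max_k = min(n - 1, p)
    if k is not None:
        n_comp = min(int(k), max_k)
        pca = _SkPCA(n_components=n_comp, svd_solver="full")
    else:
        if variance_target is None or not (0 < variance_target <= 1):
            raise ValueError("variance_target must lie in (0, 1]")
        pca = _SkPCA(n_components=max_k, svd_solver="full")
    pca.fit(X)
    if k is None:
        ratios = pca.explained_variance_ratio_
        n_comp = int(np.searchsorted(np.cumsum(ratios), variance_target - 1e-12) + 1)
        n_comp = min(n_comp, max_k)
    return PCAModel(
        mean_=pca.mean_.copy(),
        components_=pca.components_[:n_comp].copy(),
        explained_variance_ratio_=pca.explained_variance_ratio_[:n_comp].copy(),
    )


def project(model: PCAModel, features: GMFeatureMatrix | np.ndarray) -> np.ndarray:
    """Project (new) data onto the fitted components."""
    X = _as_matrix(features)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mean_.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.mean_.shape[0]})"
        )
    return (X - model.mean_) @ model.components_.T


# ---------------------------------------------------------------------------
# Relevance vector regression
# ---------------------------------------------------------------------------

_BETA_CAP = 1e12


@dataclass
class RVRModel:
    """Fitted sparse Bayesian regression model.

    ``active`` indexes the retained columns of the original design;
    column 0 is the bias, which is never pruned.
    """

    kernel: str = "linear"
    rbf_width: float | None = None
    relevance_vectors: np.ndarray | None = None  # training rows (kernel mode)
    active: np.ndarray = field(default_factory=lambda: np.array([0]))
    weights: np.ndarray = field(default_factory=lambda: np.zeros(1))
    alpha: np.ndarray = field(default_factory=lambda: np.ones(1))
    beta: float = 1.0
    converged: bool = True
    n_iter: int = 0
    log_evidence: float = np.nan
    n_features_in: int = 0

    @property
    def bias(self) -> float:
        return float(self.weights[0])


def rvr_log_evidence(
    Phi: np.ndarray, y: np.ndarray, alpha: np.ndarray, beta: float
) -> float:
    """Log marginal likelihood of targets under the sparse Bayesian model.

    ``C = I/beta + Phi diag(1/alpha) Phi^T``; returns
    ``-1/2 (N log 2pi + log|C| + y^T C^-1 y)``.
    """
    Phi = np.asarray(Phi, float)
    y = np.asarray(y, float)
    alpha = np.asarray(alpha, float)
    n = len(y)
    C = np.eye(n) / beta + (Phi / alpha) @ Phi.T
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    sol = np.linalg.solve(C, y)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + y @ sol))


def sparse_bayes_fit(
    Phi: np.ndarray,
    y: np.ndarray,
    *,
    update_beta: bool = True,
    beta_init: float | None = None,
    prune_threshold: float = 1e9,
    tol: float = 1e-6,
    max_iter: int = 1000,
    protect: tuple[int, ...] = (0,),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    """Evidence maximization over (alpha, beta) for an arbitrary design.

    Iterates the fixed-point updates ``gamma_i = 1 - alpha_i Sigma_ii``,
    ``alpha_i = gamma_i / mu_i^2`` and
    ``beta = (N - sum gamma) / ||y - Phi mu||^2`` with pruning of basis
    functions whose alpha exceeds `prune_threshold` (columns listed in
    `protect` are kept regardless).  Convergence: maximum relative change of
    alpha over retained functions below `tol`.

    Returns ``(active, mu, alpha, beta, converged, n_iter)`` where `active`
    indexes the retained columns of `Phi`.
    """
    Phi = np.asarray(Phi, float)
    y = np.asarray(y, float)
    if not np.isfinite(Phi).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in design matrix or targets")
    n, m = Phi.shape
    if n < 3:
        raise ValueError("sparse Bayesian fit needs at least 3 samples")

    active = np.arange(m)
    alpha = np.full(m, 1e-6)
    var_y = float(np.var(y))
    beta = beta_init if beta_init is not None else 1.0 / max(0.1 * var_y, 1e-6)
    beta = min(beta, _BETA_CAP)

    mu = np.zeros(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = Phi[:, active]
        A = np.diag(alpha[active])
        H = beta * (P.T @ P) + A
        try:
            Sigma = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Sigma = np.linalg.pinv(H)
        mu_act = beta * (Sigma @ (P.T @ y))
        gamma = 1.0 - alpha[active] * np.diag(Sigma)
        gamma = np.clip(gamma, 1e-12, None)
        new_alpha = gamma / np.maximum(mu_act**2, 1e-300)

        if update_beta:
            resid = y - P @ mu_act
            denom = float(resid @ resid)
            beta = float((n - gamma.sum()) / max(denom, n / _BETA_CAP))
            beta = float(np.clip(beta, 1e-12, _BETA_CAP))

        rel = np.abs(new_alpha - alpha[active]) / np.maximum(alpha[active], 1e-300)
        alpha[active] = new_alpha

        keep = (alpha[active] < prune_threshold) | np.isin(active, protect)
        if not keep.all():
            active = active[keep]
            continue  # geometry changed; refit before testing convergence
        if rel.max() < tol:
            converged = True
            break

    mu = np.zeros(m)
    P = Phi[:, active]
    A = np.diag(np.minimum(alpha[active], prune_threshold))
    H = beta * (P.T @ P) + A
    try:
        Sigma = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Sigma = np.linalg.pinv(H)
    mu[active] = beta * (Sigma @ (P.T @ y))
    return active, mu[active], alpha[active], beta, converged, it


def _rbf_kernel(X: np.ndarray, Z: np.ndarray, width: float) -> np.ndarray:
    d2 = cdist(X, Z, "sqeuclidean")
    return np.exp(-d2 / (2.0 * width**2))


def _design(
    X: np.ndarray, kernel: str, rbf_width: float | None,
    train_X: np.ndarray | None,
) -> np.ndarray:
    ones = np.ones((X.shape[0], 1))
    if kernel == "linear":
        return np.hstack([ones, X])
    if kernel == "rbf":
        if rbf_width is None or rbf_width <= 0:
            raise ValueError("rbf kernel requires a positive width")
        return np.hstack([ones, _rbf_kernel(X, train_X, rbf_width)])
    raise ValueError(f"unknown kernel {kernel!r}")


def fit_rvr(
    X: np.ndarray,
    y: np.ndarray,
    *,
    kernel: str = "linear",
    rbf_width: float | None = None,
    prune_threshold: float = 1e9,
    tol: float = 1e-6,
    max_iter: int = 1000,
    update_beta: bool = True,
    beta_init: float | None = None,
) -> RVRModel:
    """Fit relevance vector regression of targets `y` on inputs `X`."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if X.shape[0] != len(y):
        raise ValueError("X and y lengths differ")
    Phi = _design(X, kernel, rbf_width, X)
    active, mu, alpha, beta, converged, n_iter = sparse_bayes_fit(
        Phi, y, update_beta=update_beta, beta_init=beta_init,
        prune_threshold=prune_threshold, tol=tol, max_iter=max_iter,
    )
    if not converged:
        warnings.warn(
            f"RVR evidence maximization did not converge in {n_iter} iterations; "
            "returning best iterate", RuntimeWarning, stacklevel=2,
        )
    rv = None
    if kernel == "rbf":
        # retained basis functions beyond the bias correspond to training rows
        rv = X[active[active > 0] - 1]
    log_ev = rvr_log_evidence(Phi[:, active], y, alpha, beta)
    return RVRModel(
        kernel=kernel, rbf_width=rbf_width, relevance_vectors=rv,
        active=active, weights=mu, alpha=alpha, beta=beta,
        converged=converged, n_iter=n_iter, log_evidence=log_ev,
        n_features_in=X.shape[1],
    )


def predict_rvr(model: RVRModel, X: np.ndarray) -> np.ndarray:
    """Predict targets for new inputs; deterministic given the model."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match model "
            f"({model.n_features_in})"
        )
    if model.kernel == "linear":
        Phi = np.hstack([np.ones((X.shape[0], 1)), X])
        return Phi[:, model.active] @ model.weights
    K = _rbf_kernel(X, model.relevance_vectors, model.rbf_width) \
        if model.relevance_vectors is not None and len(model.relevance_vectors) \
        else np.zeros((X.shape[0], 0))
    has_bias = model.active[0] == 0
    out = np.zeros(X.shape[0])
    w = model.weights
    if has_bias:
        out += w[0]
        w = w[1:]
    return out + K @ w


def load_nifti_features(
    paths: list, subject_ids: list | np.ndarray | None = None,
    *, mask_threshold: float = 0.0,
) -> GMFeatureMatrix:
    """Build a feature matrix from one 3-D GM probability volume per subject.

    Volumes are flattened; voxels whose across-subject mean probability is
    <= `mask_threshold` are dropped.  Values are clipped to [0, 1].  All
    volumes must share one shape.  Requires nibabel.
    """
    import nibabel as nib

    vols = []
    shape = None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.get_fdata(), dtype=float)
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(
                f"volume {p} has shape {data.shape}, expected {shape}"
            )
        vols.append(data.ravel())
    X = np.clip(np.vstack(vols), 0.0, 1.0)
    keep = X.mean(axis=0) > mask_threshold
    if keep.sum() < 2:
        raise ValueError("mask leaves fewer than 2 voxels; lower mask_threshold")
    ids = np.asarray(subject_ids) if subject_ids is not None \
        else np.arange(1, len(paths) + 1)
    return GMFeatureMatrix(values=X[:, keep], subject_ids=ids)


# ---------------------------------------------------------------------------
# Cross-validated estimation
# ---------------------------------------------------------------------------

@dataclass
class CrossValPlan:
    """Fold assignment used for the leave-k-out estimation."""

    assignments: pd.DataFrame  # subject_id, stratum, fold
    k: int
    sex_split: bool
    seed: int


def leave_k_out_estimate(
    cohort: pd.DataFrame,
    features: GMFeatureMatrix | np.ndarray,
    *,
    k: int = 10,
    sex_split: bool = True,
    seed: int = 0,
    variance_target: float = 0.95,
    n_components: int | None = None,
    kernel: str = "linear",
    rbf_width: float | None = None,
    rvr_tol: float = 1e-4,
    rvr_max_iter: int = 300,
) -> tuple[np.ndarray, CrossValPlan]:
    """Cross-validated brain-age estimation.

    Within each stratum (each sex when `sex_split` is on, otherwise the full
    cohort), subjects are shuffled once with `seed` and chunked into
    consecutive folds of `k` (the remainder forms a smaller final fold).
    For each fold, PCA and the RVR are fit on the remaining same-stratum
    subjects only — no information from held-out subjects leaks into their
    own estimates — and ages of the held-out fold are predicted.

    Returns per-subject estimated ages (cohort row order) and the plan.
    """
    X = _as_matrix(features)
    n = len(cohort)
    if X.shape[0] != n:
        raise ValueError("phenotype table and feature matrix disagree in length")
    ages = cohort["age"].to_numpy(float)
    if sex_split:
        strata = cohort["sex"].astype(str).to_numpy()
    else:
        strata = np.full(n, "all")

    rng = np.random.default_rng(seed)
    estimated = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    for stratum in sorted(set(strata)):
        idx = np.flatnonzero(strata == stratum)
        if len(idx) <= k:
            raise ValueError(
                f"stratum {stratum!r} has only {len(idx)} subjects (need > k={k}); "
                "disable sex_split or reduce k"
            )
        perm = rng.permutation(idx)
        folds = [perm[i:i + k] for i in range(0, len(perm), k)]
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(idx, test_idx)
            pca = fit_pca(X[train_idx],
                          variance_target=None if n_components else variance_target,
                          k=n_components)
            Xtr = project(pca, X[train_idx])
            Xte = project(pca, X[test_idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = fit_rvr(Xtr, ages[train_idx], kernel=kernel,
                                rbf_width=rbf_width, tol=rvr_tol,
                                max_iter=rvr_max_iter)
            estimated[test_idx] = predict_rvr(model, Xte)
            fold_of[test_idx] = f

    plan = CrossValPlan(
        assignments=pd.DataFrame(
            {
                "subject_id": cohort["subject_id"].to_numpy()
                if "subject_id" in cohort else np.arange(n),
                "stratum": strata,
                "fold": fold_of,
            }
        ),
        k=k, sex_split=sex_split, seed=seed,
    )
    return estimated, plan


# ---------------------------------------------------------------------------
# Gap formation, detrending, performance
# ---------------------------------------------------------------------------

@dataclass
class BrainAgeResult:
    estimated_age: np.ndarray
    raw_gap: np.ndarray
    brainage: np.ndarray  # detrended gap
    detrend_coefficients: np.ndarray  # (intercept, linear, quadratic)


def compute_brainage(estimated: np.ndarray, chronological: np.ndarray) -> np.ndarray:
    """Raw brain-age gap: estimated minus chronological age (years)."""
    estimated = np.asarray(estimated, float)
    chronological = np.asarray(chronological, float)
    if estimated.shape != chronological.shape:
        raise ValueError("estimated and chronological age vectors differ in length")
    return estimated - chronological


def detrend_quadratic(
    gaps: np.ndarray, ages: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove a least-squares quadratic age trend from the raw gaps.

    Returns (residuals, coefficients) with coefficients ordered
    (intercept, linear, quadratic).  Residuals are exactly orthogonal to
    {1, age, age^2} and therefore have zero mean.
    """
    gaps = np.asarray(gaps, float)
    ages = np.asarray(ages, float)
    if len(gaps) != len(ages):
        raise ValueError("gaps and ages differ in length")
    if len(gaps) < 4:
        raise ValueError("quadratic detrending needs at least 4 subjects")
    if np.ptp(ages) == 0:
        raise ValueError("all ages identical; quadratic detrend design is collinear")
    design = np.column_stack([np.ones_like(ages), ages, ages**2])
    coef, *_ = np.linalg.lstsq(design, gaps, rcond=None)
    resid = gaps - design @ coef
    # one Newton refinement keeps orthogonality tight despite age^2 scaling
    corr, *_ = np.linalg.lstsq(design, resid, rcond=None)
    coef = coef + corr
    resid = resid - design @ corr
    return resid, coef


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class PerformanceReport:
    """Accuracy summary of a brain-age estimation.

    MAE is the mean absolute detrended gap (each gap reads as the estimation
    error for that subject).  `r_undefined` flags correlations that are
    undefined because one input had zero variance.
    """

    mae: float
    r_chron_estimated: float | None
    r_chron_brainage: float | None
    r2_estimated_on_chron: float | None
    mean_brainage: float
    sd_brainage: float
    n: int
    r_undefined: bool = False
    by_stratum: dict[str, "PerformanceReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "mae": self.mae,
            "r_chron_estimated": self.r_chron_estimated,
            "r_chron_brainage": self.r_chron_brainage,
            "r2_estimated_on_chron": self.r2_estimated_on_chron,
            "mean_brainage": self.mean_brainage,
            "sd_brainage": self.sd_brainage,
            "n": self.n,
            "r_undefined": self.r_undefined,
        }
        if self.by_stratum:
            d["by_stratum"] = {k: v.to_dict() for k, v in self.by_stratum.items()}
        return d


def performance_report(
    chronological: np.ndarray,
    estimated: np.ndarray,
    brainage: np.ndarray,
    strata: np.ndarray | None = None,
) -> PerformanceReport:
    chronological = np.asarray(chronological, float)
    estimated = np.asarray(estimated, float)
    brainage = np.asarray(brainage, float)
    if not (len(chronological) == len(estimated) == len(brainage)):
        raise ValueError("input vectors differ in length")

    r_ce = _pearson(chronological, estimated)
    r_cb = _pearson(chronological, brainage)
    r2 = None if r_ce is None else r_ce**2
    report = PerformanceReport(
        mae=float(np.mean(np.abs(brainage))),
        r_chron_estimated=r_ce,
        r_chron_brainage=r_cb,
        r2_estimated_on_chron=r2,
        mean_brainage=float(np.mean(brainage)),
        sd_brainage=float(np.std(brainage, ddof=1)) if len(brainage) > 1 else 0.0,
        n=len(brainage),
        r_undefined=r_ce is None or r_cb is None,
    )
    if strata is not None:
        strata = np.asarray(strata)
        for s in sorted(set(strata.tolist())):
            m = strata == s
            if m.sum() >= 2:
                report.by_stratum[str(s)] = performance_report(
                    chronological[m], estimated[m], brainage[m]
                )
    return report
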