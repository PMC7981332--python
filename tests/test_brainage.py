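"""PCA, relevance vector regression, cross-validation, detrending and
performance reporting."""

import dataclasses
import warnings

import numpy as np
import pytest

from brainagekit.brainage import (
    RVRModel,
    compute_brainage,
    detrend_quadratic,
    fit_pca,
    fit_rvr,
    leave_k_out_estimate,
    performance_report,
    predict_rvr,
    project,
    rvr_log_evidence,
    sparse_bayes_fit,
)
from brainagekit.synthdata import SimulationConfig, generate_cohort

ZERO_EFFECTS = {k: 0.0 for k in
                ("pack_years", "alcohol_g_month", "met_score", "social_index")}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_rank_two_data_explained_by_two_components():
    rng = np.random.default_rng(0)
    basis = rng.normal(size=(2, 7))
    X = rng.normal(size=(30, 2)) @ basis
    model = fit_pca(X, k=2)
    assert model.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-10)


def test_projection_of_training_mean_is_zero():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 5))
    model = fit_pca(X, k=3)
    np.testing.assert_allclose(project(model, model.mean_), 0.0, atol=1e-10)


def test_loadings_match_covariance_eigendecomposition():
    """Components and explained variances agree with a direct
    eigendecomposition of the sample covariance (up to sign)."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(10, 5))
    model = fit_pca(X, k=5)
    C = np.cov(X, rowvar=False)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    ratios = w / w.sum()
    np.testing.assert_allclose(model.explained_variance_ratio_, ratios[:5],
                               atol=1e-8)
    for i in range(5):
        cos = abs(model.components_[i] @ V[:, i])
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_full_rank_projection_reconstructs_data():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(9, 4))
    model = fit_pca(X, k=4)
    scores = project(model, X)
    recon = scores @ model.components_ + model.mean_
    np.testing.assert_allclose(recon, X, atol=1e-8)


def test_loadings_are_orthonormal():
    rng = np.random.default_rng(4)
    model = fit_pca(rng.normal(size=(20, 6)), variance_target=0.95)
    gram = model.components_ @ model.components_.T
    np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)
    assert (np.diff(model.explained_variance_ratio_) <= 1e-12).all()


def test_project_rejects_dimension_mismatch():
    model = fit_pca(np.random.default_rng(5).normal(size=(8, 4)), k=2)
    with pytest.raises(ValueError, match="dimension"):
        project(model, np.zeros((3, 7)))


def test_variance_target_outside_unit_interval_errors():
    with pytest.raises(ValueError):
        fit_pca(np.zeros((5, 3)) + np.random.default_rng(6).normal(size=(5, 3)),
                variance_target=1.5)


# ---------------------------------------------------------------------------
# RVR
# ---------------------------------------------------------------------------

def test_noise_free_line_is_interpolated():
    x = np.linspace(0, 10, 25)[:, None]
    y = 2 * x[:, 0] + 1
    model = fit_rvr(x, y)
    assert np.abs(predict_rvr(model, x) - y).max() < 1e-3


def test_constant_targets_predicted_by_bias():
    x = np.linspace(-3, 3, 20)[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_rvr(x, np.full(20, 4.5))
    assert np.abs(predict_rvr(model, x) - 4.5).max() < 1e-6


def test_manual_zero_weight_model_predicts_bias():
    model = RVRModel(kernel="linear", active=np.array([0]),
                     weights=np.array([3.0]), n_features_in=2)
    np.testing.assert_allclose(predict_rvr(model, np.ones((4, 2))), 3.0)


def test_duplicate_rows_get_identical_predictions():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 3))
    y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.1, 30)
    model = fit_rvr(X, y)
    Xdup = np.vstack([X[0], X[0]])
    p = predict_rvr(model, Xdup)
    assert p[0] == p[1]


def test_predict_rejects_dimension_mismatch():
    model = fit_rvr(np.random.default_rng(8).normal(size=(10, 2)),
                    np.arange(10.0))
    with pytest.raises(ValueError, match="dimension"):
        predict_rvr(model, np.zeros((3, 5)))


def test_non_finite_inputs_rejected():
    X = np.ones((10, 2))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        fit_rvr(X, np.arange(10.0))


def test_evidence_matches_brute_force_grid_maximum():
    """Converged marginal likelihood equals a brute-force grid maximization
    of the evidence over per-weight precisions (beta held fixed)."""
    rng = np.random.default_rng(9)
    n = 12
    Phi = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    w_true = np.array([1.0, 2.0, -1.5])
    beta = 1.0 / 0.3**2
    y = Phi @ w_true + rng.normal(0, 0.3, n)

    _, _, alpha_fit, _, conv, _ = sparse_bayes_fit(
        Phi, y, update_beta=False, beta_init=beta, prune_threshold=np.inf,
        tol=1e-10, max_iter=5000, protect=(0,),
    )
    assert conv
    fit_ev = rvr_log_evidence(Phi, y, alpha_fit, beta)

    # iteratively refined grid over log10(alpha), 3 dimensions
    centers = np.zeros(3)
    half_width = 4.0
    best = (-np.inf, None)
    for _ in range(4):
        axes = [centers[d] + np.linspace(-half_width, half_width, 13)
                for d in range(3)]
        for a0 in axes[0]:
            for a1 in axes[1]:
                for a2 in axes[2]:
                    ev = rvr_log_evidence(Phi, y, 10.0 ** np.array([a0, a1, a2]),
                                          beta)
                    if ev > best[0]:
                        best = (ev, np.array([a0, a1, a2]))
        centers = best[1]
        half_width /= 6.0
    assert fit_ev == pytest.approx(best[0], abs=1e-3)


def test_linear_kernel_matches_bayesian_ridge_closed_form():
    """Without pruning the fit degenerates to Bayesian linear regression:
    predictions match the ridge-type closed form at the converged
    (alpha, beta)."""
    rng = np.random.default_rng(10)
    X = rng.normal(size=(40, 3))
    y = X @ [2.0, 0.0, -1.0] + rng.normal(0, 0.5, 40)
    model = fit_rvr(X, y, prune_threshold=np.inf, tol=1e-10, max_iter=5000)
    Phi = np.hstack([np.ones((40, 1)), X])
    A = np.diag(model.alpha)
    mu = model.beta * np.linalg.solve(model.beta * Phi.T @ Phi + A, Phi.T @ y)
    np.testing.assert_allclose(predict_rvr(model, X), Phi @ mu, atol=1e-6)


def test_rbf_kernel_fits_nonlinear_function():
    rng = np.random.default_rng(11)
    x = np.linspace(-3, 3, 60)[:, None]
    y = np.sin(x[:, 0]) + rng.normal(0, 0.05, 60)
    model = fit_rvr(x, y, kernel="rbf", rbf_width=1.0)
    pred = predict_rvr(model, x)
    assert np.mean(np.abs(pred - np.sin(x[:, 0]))) < 0.1
    # sparsity: some basis functions pruned
    assert len(model.active) < 61


# ---------------------------------------------------------------------------
# leave-k-out
# ---------------------------------------------------------------------------

def _tiny_cohort(n=20, seed=0, **kwargs):
    cfg = SimulationConfig(n_subjects=n, seed=seed, n_features=16,
                           effect_months=ZERO_EFFECTS, **kwargs)
    return generate_cohort(cfg)


def test_twenty_subjects_k10_gives_two_folds_each_estimated_once():
    c = _tiny_cohort(20)
    est, plan = leave_k_out_estimate(c.phenotypes, c.features, k=10,
                                     sex_split=False, seed=0)
    assert np.isfinite(est).all()
    assert set(plan.assignments["fold"]) == {0, 1}
    assert (plan.assignments["fold"].value_counts() == 10).all()


def test_sex_split_folds_stay_within_stratum():
    c = _tiny_cohort(60, seed=1)
    est, plan = leave_k_out_estimate(c.phenotypes, c.features, k=10,
                                     sex_split=True, seed=0)
    assert np.isfinite(est).all()
    a = plan.assignments
    # each (stratum, fold) pair contains only one sex, and folds partition
    # each stratum
    for stratum, sub in a.groupby("stratum"):
        sexes = c.phenotypes.set_index("subject_id").loc[
            sub["subject_id"], "sex"]
        assert sexes.nunique() == 1
        assert sub.groupby("fold").size().sum() == len(sub)


def test_small_stratum_raises_actionable_error():
    c = _tiny_cohort(12, seed=2)
    with pytest.raises(ValueError, match="sex_split"):
        leave_k_out_estimate(c.phenotypes, c.features, k=10, sex_split=True)


def test_noise_free_monotone_cohort_estimated_below_one_year_mae():
    """With an invertible, noise-free age->feature map the cross-validated
    MAE stays below a year."""
    cfg = SimulationConfig(n_subjects=300, seed=3, feature_noise_sd=0.0,
                           estimator_noise_sd=0.0, effect_months=ZERO_EFFECTS,
                           age_trend=(-0.004, 0.0), n_features=16)
    c = generate_cohort(cfg)
    est, _ = leave_k_out_estimate(c.phenotypes, c.features, k=10,
                                  sex_split=True, seed=3)
    ages = c.phenotypes["age"].to_numpy()
    assert np.mean(np.abs(est - ages)) < 1.0


def test_estimates_depend_on_anatomy_not_age_label():
    """A subject whose anatomy corresponds to a much younger brain is
    estimated near its effective (anatomical) age, not its chronological
    age — its own age label cannot leak into its estimate."""
    cfg = SimulationConfig(n_subjects=200, seed=4, feature_noise_sd=0.0,
                           estimator_noise_sd=0.0, effect_months=ZERO_EFFECTS,
                           age_trend=(-0.004, 0.0), n_features=16)
    c = generate_cohort(cfg)
    # plant a large negative offset for the oldest subject and rebuild features
    i = int(np.argmax(c.phenotypes["age"].to_numpy()))
    c.true_offset[i] = -30.0
    from brainagekit.synthdata import generate_gm_features
    c.features = generate_gm_features(c, cfg)
    est, _ = leave_k_out_estimate(c.phenotypes, c.features, k=10,
                                  sex_split=False, seed=4)
    age_i = c.phenotypes["age"].iloc[i]
    assert abs(est[i] - (age_i - 30.0)) < 3.0
    assert est[i] < age_i - 20.0


def test_other_stratum_estimates_untouched_by_feature_changes():
    """Corrupting every female subject's features leaves male estimates
    bit-identical (strata are fully separate estimation problems)."""
    c = _tiny_cohort(80, seed=5)
    est1, _ = leave_k_out_estimate(c.phenotypes, c.features, k=10,
                                   sex_split=True, seed=1)
    vals = c.features.values.copy()
    female = (c.phenotypes["sex"] == "female").to_numpy()
    rng = np.random.default_rng(99)
    vals[female] = rng.uniform(0, 1, vals[female].shape)
    feats2 = dataclasses.replace(c.features, values=vals)
    est2, _ = leave_k_out_estimate(c.phenotypes, feats2, k=10,
                                   sex_split=True, seed=1)
    np.testing.assert_array_equal(est1[~female], est2[~female])
    assert not np.allclose(est1[female], est2[female])


def test_nifti_volumes_flatten_into_masked_features(tmp_path):
    nib = pytest.importorskip("nibabel")
    from brainagekit.brainage import load_nifti_features

    rng = np.random.default_rng(20)
    paths = []
    for i in range(3):
        vol = rng.uniform(0, 1, (4, 4, 4))
        vol[0, 0, :] = 0.0  # background voxels, masked out by threshold
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        p = tmp_path / f"sub{i}.nii.gz"
        nib.save(img, str(p))
        paths.append(p)
    feats = load_nifti_features(paths, subject_ids=[10, 11, 12],
                                mask_threshold=0.05)
    assert feats.n_subjects == 3
    assert feats.n_features == 64 - 4  # zeroed column dropped by the mask
    assert feats.values.min() >= 0 and feats.values.max() <= 1


# ---------------------------------------------------------------------------
# gap, detrend, performance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("est, chron, expected",
                         [(70.0, 65.0, 5.0), (60.5, 63.0, -2.5)])
def test_raw_gap_is_estimated_minus_chronological(est, chron, expected):
    assert compute_brainage(np.array([est]), np.array([chron]))[0] == expected


def test_perfect_estimation_gives_zero_gaps():
    ages = np.linspace(20, 80, 10)
    np.testing.assert_array_equal(compute_brainage(ages, ages), np.zeros(10))


def test_exact_quadratic_trend_is_removed_completely():
    ages = np.linspace(20, 80, 40)
    gaps = 1.5 - 0.1 * ages + 0.002 * ages**2
    resid, coef = detrend_quadratic(gaps, ages)
    np.testing.assert_allclose(resid, 0.0, atol=1e-8)
    np.testing.assert_allclose(coef, [1.5, -0.1, 0.002], atol=1e-6)


def test_detrended_gaps_have_zero_mean_and_age_orthogonality():
    rng = np.random.default_rng(12)
    ages = rng.uniform(20, 85, 200)
    gaps = rng.normal(0, 5, 200) + 0.05 * ages
    resid, _ = detrend_quadratic(gaps, ages)
    assert abs(resid.mean()) < 1e-10
    for col in (ages, ages**2):
        c = np.corrcoef(resid, col)[0, 1]
        assert abs(c) < 1e-8


def test_detrend_coefficients_match_normal_equations_oracle():
    ages = np.array([20.0, 30.0, 40.0, 55.0, 70.0, 85.0])
    gaps = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 2.0])
    D = np.column_stack([np.ones(6), ages, ages**2])
    oracle = np.linalg.solve(D.T @ D, D.T @ gaps)  # hand 3x3 normal equations
    _, coef = detrend_quadratic(gaps, ages)
    np.testing.assert_allclose(coef, oracle, atol=1e-8)


def test_detrend_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="collinear"):
        detrend_quadratic(np.arange(5.0), np.full(5, 50.0))
    with pytest.raises(ValueError):
        detrend_quadratic(np.arange(3.0), np.arange(3.0))


def test_performance_report_hand_computed_values():
    chron = np.array([50.0, 60.0, 70.0, 80.0, 90.0])
    est = np.array([52.0, 58.0, 71.0, 79.0, 95.0])
    ba = est - chron
    rep = performance_report(chron, est, ba)
    assert rep.mae == pytest.approx(np.mean([2, 2, 1, 1, 5]))
    assert rep.r_chron_estimated == pytest.approx(
        np.corrcoef(chron, est)[0, 1], abs=1e-12)
    assert rep.r2_estimated_on_chron == pytest.approx(
        np.corrcoef(chron, est)[0, 1] ** 2, abs=1e-12)


def test_perfect_estimation_performance():
    chron = np.linspace(30, 80, 20)
    rep = performance_report(chron, chron, np.zeros(20))
    assert rep.mae == 0.0
    assert rep.r_chron_estimated == pytest.approx(1.0)
    assert rep.r2_estimated_on_chron == pytest.approx(1.0)


def test_symmetric_gaps_mae():
    rep = performance_report(np.array([60.0, 70.0]), np.array([58.0, 72.0]),
                             np.array([-2.0, 2.0]))
    assert rep.mae == 2.0


def test_zero_variance_correlation_flagged_not_silent():
    rep = performance_report(np.full(5, 60.0), np.arange(5.0), np.arange(5.0))
    assert rep.r_undefined
    assert rep.r_chron_estimated is None
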