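"""Transfer estimator, baselines, CV tuning, adaptive aggregation."""

import numpy as np
import pytest

from transrr.losses import quadratic, smoothed_huber
from transrr.solvers import StudyData, fit_robust_ridge
from transrr.transfer import (
    DEFAULT_PENALTY_GRID,
    DEFAULT_THETA_GRID,
    CoefficientPair,
    adaptive_trans_rr,
    cv_tune_penalty,
    pooled_rr,
    single_rr,
    trans_rr,
)


def _make_pair(rng, n=40, n1=60, p=25, noise=0.5):
    w0 = rng.standard_normal(p) / np.sqrt(p)
    beta0 = w0 + 0.1 * rng.standard_normal(p) / np.sqrt(p)
    Xs = rng.standard_normal((n1, p))
    Xt = rng.standard_normal((n, p))
    source = StudyData(Xs, Xs @ w0 + noise * rng.standard_normal(n1))
    target = StudyData(Xt, Xt @ beta0 + noise * rng.standard_normal(n))
    return target, source, beta0, w0


def test_coefficient_pair_invariants(rng):
    beta0 = rng.standard_normal(10)
    w0 = rng.standard_normal(10)
    pair = CoefficientPair(beta0, w0)
    np.testing.assert_allclose(pair.delta0, beta0 - w0)
    assert pair.h == pytest.approx(np.linalg.norm(beta0 - w0))


def test_transfer_sum_identity(sh_loss, rng):
    target, source, *_ = _make_pair(rng)
    fit = trans_rr(target, source, sh_loss, sh_loss, tau=1.0, tau1=1.0)
    np.testing.assert_array_equal(fit.beta_hat, fit.w_hat + fit.delta_hat)


def test_perfect_source_fit_gives_zero_correction(sh_loss, rng):
    """If the target response is exactly the stage-1 prediction, the
    correction stage has nothing to explain and returns zero."""
    target, source, *_ = _make_pair(rng)
    stage1 = fit_robust_ridge(source, sh_loss, tau=1.0)
    target_exact = StudyData(target.X, target.X @ stage1.coef)
    fit = trans_rr(target_exact, source, sh_loss, sh_loss, tau=0.5, tau1=1.0)
    np.testing.assert_allclose(fit.delta_hat, 0.0, atol=1e-10)
    np.testing.assert_allclose(fit.beta_hat, stage1.coef, atol=1e-10)


def test_quadratic_two_stage_composition(quad_loss, rng):
    """With quadratic losses both stages reduce to explicit linear algebra."""
    target, source, *_ = _make_pair(rng)
    tau, tau1 = 0.8, 1.3

    def ridge(X, y, t):
        n, p = X.shape
        return np.linalg.solve(X.T @ X / n + t * np.eye(p), X.T @ y / n)

    w = ridge(source.X, source.y, tau1)
    delta = ridge(target.X, target.y - target.X @ w, tau)
    fit = trans_rr(target, source, quad_loss, quad_loss, tau=tau, tau1=tau1)
    np.testing.assert_allclose(fit.beta_hat, w + delta, atol=1e-9)


def test_single_rr_is_plain_robust_ridge(sh_loss, rng):
    target, *_ = _make_pair(rng)
    np.testing.assert_array_equal(
        single_rr(target, sh_loss, 0.9).coef,
        fit_robust_ridge(target, sh_loss, 0.9).coef,
    )


def test_pooled_rr_on_duplicated_target_equals_single(sh_loss, rng):
    """The objective is a per-row average, so doubling the sample changes
    nothing."""
    target, *_ = _make_pair(rng)
    pooled = pooled_rr(target, target, sh_loss, 0.7)
    single = single_rr(target, sh_loss, 0.7)
    np.testing.assert_allclose(pooled.coef, single.coef, atol=1e-9)


def test_dimension_mismatch_rejected(sh_loss, rng):
    target, source, *_ = _make_pair(rng)
    bad = StudyData(source.X[:, :-1], source.y)
    with pytest.raises(ValueError):
        trans_rr(target, bad, sh_loss, sh_loss, tau=1.0, tau1=1.0)
    with pytest.raises(ValueError):
        pooled_rr(target, bad, sh_loss, 1.0)


def test_default_penalty_grid_shape():
    grid = np.asarray(DEFAULT_PENALTY_GRID)
    assert len(grid) == 9
    assert grid.min() == pytest.approx(1 / 9)
    assert grid.max() == pytest.approx(9.0)


def test_cv_single_point_grid_returns_it(sh_loss, rng):
    target, *_ = _make_pair(rng)
    assert cv_tune_penalty(target, sh_loss, grid=[0.42], rng=rng) == 0.42


def test_cv_criteria_agree_on_clean_gaussian_data(sh_loss):
    """On noiseless data both criteria rank penalties identically (any
    monotone function of |resid| picks the same argmin)."""
    rng = np.random.default_rng(7)
    p, n = 10, 200
    beta = rng.standard_normal(p)
    X = rng.standard_normal((n, p))
    data = StudyData(X, X @ beta)
    grid = [0.01, 0.1, 1.0, 10.0]
    mae = cv_tune_penalty(data, sh_loss, grid, criterion="mae", rng=np.random.default_rng(3))
    mse = cv_tune_penalty(data, sh_loss, grid, criterion="mse", rng=np.random.default_rng(3))
    assert mae == mse == 0.01


def test_cv_input_validation(sh_loss, rng):
    target, *_ = _make_pair(rng)
    with pytest.raises(ValueError):
        cv_tune_penalty(target, sh_loss, grid=[], rng=rng)
    with pytest.raises(ValueError):
        cv_tune_penalty(target, sh_loss, K=1, rng=rng)
    small = StudyData(np.ones((3, 2)), np.ones(3))
    with pytest.raises(ValueError):
        cv_tune_penalty(small, sh_loss, K=5, rng=rng)


def test_theta_endpoints_recover_base_estimators(sh_loss, rng):
    target, source, *_ = _make_pair(rng)
    fit = adaptive_trans_rr(
        target, source, sh_loss, tau1=1.0, tau=1.0, tau_st=1.0, rng=rng
    )
    beta_hat = fit.transfer_fit.beta_hat
    beta_st = fit.single_fit.coef
    np.testing.assert_array_equal(
        1.0 * beta_hat + 0.0 * beta_st, beta_hat
    )
    np.testing.assert_array_equal(fit.beta_ada,
        fit.theta_hat * beta_hat + (1 - fit.theta_hat) * beta_st)
    assert fit.theta_hat in fit.theta_grid
    assert fit.cv_losses[fit.theta_hat] == min(fit.cv_losses.values())


def test_identical_fits_tie_break_to_zero(sh_loss, rng):
    """When the transfer and single fits coincide, every theta ties and the
    tie-break prefers the single-study fallback theta = 0."""
    target, *_ = _make_pair(rng)
    # source == target with equal penalties makes stage-1 fit the target fit;
    # simpler: degenerate source that contributes nothing (y == 0 => w_hat ~ 0)
    null_source = StudyData(target.X, np.zeros(target.n))
    fit = adaptive_trans_rr(
        target, null_source, sh_loss, tau1=1e8, tau=1.0, tau_st=1.0, rng=rng
    )
    np.testing.assert_allclose(fit.transfer_fit.beta_hat, fit.single_fit.coef, atol=1e-6)
    assert fit.theta_hat == 0.0


def test_oracle_source_beats_corrupted_single_fit(sh_loss):
    """Noiseless target whose stage-1 fit is essentially exact, against a
    single-task fit wrecked by a huge penalty: the weight goes to 1."""
    rng = np.random.default_rng(11)
    p, n, n1 = 20, 50, 4000
    beta0 = rng.standard_normal(p) / np.sqrt(p)
    Xs = rng.standard_normal((n1, p))
    source = StudyData(Xs, Xs @ beta0 + 0.001 * rng.standard_normal(n1))
    Xt = rng.standard_normal((n, p))
    target = StudyData(Xt, Xt @ beta0)
    fit = adaptive_trans_rr(
        target, source, sh_loss, tau1=1e-6, tau=1e-6, tau_st=1e6, rng=rng
    )
    assert fit.theta_hat == 1.0


def test_theta_grid_must_contain_endpoints(sh_loss, rng):
    target, source, *_ = _make_pair(rng)
    with pytest.raises(ValueError):
        adaptive_trans_rr(
            target, source, sh_loss, tau1=1, tau=1, tau_st=1,
            theta_grid=(0.0, 0.5), rng=rng,
        )
    assert 0.0 in DEFAULT_THETA_GRID and 1.0 in DEFAULT_THETA_GRID
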