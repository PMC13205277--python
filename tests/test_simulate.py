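"""Data generators and experiment runners: moments, determinism, patterns."""

import numpy as np
import pytest

from transrr.losses import smoothed_huber
from transrr.simulate import (
    gen_coefficients,
    gen_study,
    run_comparison_experiment,
    run_validity_experiment,
)
from transrr.solvers import StudyData, fit_robust_ridge


def test_normalized_scheme_controls_discrepancy(rng):
    pair = gen_coefficients("normalized", p=400, n=400, cd=0.0, rng=rng)
    assert np.linalg.norm(pair.beta0) == pytest.approx(1.0, abs=1e-12)
    assert pair.h == pytest.approx(1.0, abs=1e-12)
    pair = gen_coefficients("normalized", p=400, n=400, cd=-2.0, rng=rng)
    assert pair.h == pytest.approx(np.exp(-2.0), abs=1e-12)


def test_diffuse_scheme_norm_scaling(rng):
    """Unif(0,1) entries over sqrt(n): ||beta0||^2 concentrates near p/(3n)."""
    p = n = 2000
    pair = gen_coefficients("diffuse", p=p, n=n, rng=rng)
    assert np.sum(pair.beta0**2) == pytest.approx(p / (3 * n), rel=0.05)


def test_study_dimensions_and_latents(rng):
    sim = gen_study("III", p=7, n=11, role="target", coef=np.zeros(7), rng=rng)
    assert sim.data.X.shape == (11, 7)
    assert sim.data.y.shape == (11,)
    assert sim.eps.shape == (11,) and sim.lam.shape == (11,)
    # first half of Case III rows have unit scale
    assert np.all(sim.lam[:6] == 1.0)


def test_case2_scale_unit_second_moment(rng):
    sim = gen_study("II", p=2, n=100_000, role="target", coef=np.zeros(2), rng=rng)
    assert np.mean(sim.lam**2) == pytest.approx(1.0, rel=0.02)


def test_ar1_covariance(rng):
    sim = gen_study(
        "I", p=5, n=100_000, role="target", coef=np.zeros(5), rng=rng,
        covariance=("ar1", 0.6),
    )
    cov = sim.data.X.T @ sim.data.X / sim.data.n
    assert cov[1, 2] == pytest.approx(0.6, abs=0.02)
    assert cov[0, 2] == pytest.approx(0.36, abs=0.02)
    assert cov[3, 3] == pytest.approx(1.0, abs=0.02)


def test_source_role_has_larger_noise(rng):
    tgt = gen_study("I", p=2, n=50_000, role="target", coef=np.zeros(2), rng=rng)
    src = gen_study("I", p=2, n=50_000, role="source", coef=np.zeros(2), rng=rng)
    assert np.std(tgt.eps) == pytest.approx(1.0, rel=0.03)
    assert np.std(src.eps) == pytest.approx(2.0, rel=0.03)


def test_case3_row_order_immaterial_for_fits(sh_loss, rng):
    """Estimators average over rows, so shuffling Case III rows changes
    nothing."""
    sim = gen_study("III", p=30, n=60, role="target",
                    coef=rng.standard_normal(30) / 6, rng=rng)
    perm = rng.permutation(60)
    fit = fit_robust_ridge(sim.data, sh_loss, tau=1.0)
    fit_perm = fit_robust_ridge(
        StudyData(sim.data.X[perm], sim.data.y[perm]), sh_loss, tau=1.0
    )
    np.testing.assert_allclose(fit.coef, fit_perm.coef, atol=1e-9)


def test_validity_experiment_reproducible_and_consistent():
    r1 = run_validity_experiment("I", 60, 60, 120, n_reps=8, seed=42,
                                 solve_theory=False)
    r2 = run_validity_experiment("I", 60, 60, 120, n_reps=8, seed=42,
                                 solve_theory=False)
    np.testing.assert_array_equal(r1.errors_sq, r2.errors_sq)
    np.testing.assert_array_equal(r1.discrepancies, r2.discrepancies)
    assert r1.n_reps == 8 and np.all(r1.errors_sq > 0)


def test_validity_single_rep_sd_flagged():
    res = run_validity_experiment("I", 30, 30, 60, n_reps=1, seed=0,
                                  solve_theory=False)
    assert np.isnan(res.sd)


def test_comparison_runner_reproducible_and_well_formed():
    kwargs = dict(
        case="I", p=40, n=40, n1=80, cd_values=(-2.0, 1.0),
        methods=("single", "trans", "ada", "pooled"),
        n_reps=3, seed=9, grid=(0.5, 1.0), theta_grid=(0.0, 0.5, 1.0),
    )
    s1, p1 = run_comparison_experiment(**kwargs)
    s2, _ = run_comparison_experiment(**kwargs)
    assert (s1["mean_rel_err"] == s2["mean_rel_err"]).all()
    assert set(s1["method"]) == {"single", "trans", "ada", "pooled"}
    assert len(s1) == 2 * 4
    # single-study results do not depend on the discrepancy
    singles = p1[p1.method == "single"].pivot(index="rep", columns="h",
                                              values="rel_err")
    np.testing.assert_allclose(singles.iloc[:, 0], singles.iloc[:, 1])


def test_comparison_fixed_tuning_skips_cv():
    s, p = run_comparison_experiment(
        case="I", p=30, n=30, n1=60, cd_values=(0.0,),
        methods=("trans",), tuning="fixed", fixed_tau=2.5, n_reps=2, seed=1,
    )
    assert (p["tau"] == 2.5).all() and (p["tau1"] == 2.5).all()


def test_comparison_rejects_unknown_method():
    with pytest.raises(ValueError):
        run_comparison_experiment(methods=("magic",), n_reps=1)


def test_error_grows_with_dimension_ratio():
    """At matched p, the kappa = 4 design (smaller n) has a larger mean
    error than kappa = 1, and heavy tails (Case II) cost accuracy at
    matched sizes."""
    k1 = run_validity_experiment("I", 80, 80, 160, n_reps=30, seed=2,
                                 solve_theory=False)
    k4 = run_validity_experiment("I", 80, 20, 40, n_reps=30, seed=2,
                                 solve_theory=False)
    assert k4.mean > k1.mean
    heavy = run_validity_experiment("II", 80, 80, 160, n_reps=30, seed=2,
                                    solve_theory=False)
    assert heavy.mean > k1.mean


def test_heuristic_discrepancy_predictor():
    from transrr.theory import predicted_discrepancy

    assert predicted_discrepancy(0.3, 0.4) == pytest.approx(0.5)
    assert predicted_discrepancy(0.0, 0.7) == pytest.approx(0.7)
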