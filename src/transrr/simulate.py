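"""Synthetic study generators and the experiment pipelines.

Three noise scenarios are used throughout:

* **Case I** — unit predictor scale, Gaussian errors: target errors
  N(0, 1), source errors N(0, 4).
* **Case II** — elliptical-like design ``x_i = lam_i X_i`` with
  ``lam_i ~ Unif(0, sqrt(3))`` (so ``E[lam^2] = 1`` and ``cov(x_i) = I``,
  as the theory's design assumption requires) and Cauchy errors (target
  scale 1, source scale 2).
* **Case III** — first half of the rows as Case I, second half as Case II
  (rows are exchangeable for every estimator here, so the ordering is
  immaterial).

Two coefficient schemes match the two experiment families: the *diffuse*
scheme draws ``beta*, w*`` with Unif(0,1) entries and scales by
``1/sqrt(n)`` so the coefficient norms stay bounded as ``n`` grows (used
for validating the asymptotic-risk solver), and the *normalized* scheme fixes ``||beta0|| = 1`` and places the
source at a controlled distance ``h = exp(cd)`` along the constant
direction ``1_p / sqrt(p)`` (used for the positive/negative-transfer
comparison).  In both schemes the coefficients are drawn once per
configuration and held fixed across replicates; only the data are redrawn.

All randomness flows from one integer seed through named ``SeedSequence``
substreams (coefficients, per-replicate data, penalty-tuning folds, and
mixing-weight folds), keeping the weight-selection partition independent
of the tuning partitions.  Within a replicate of the comparison sweep the
target sample and the source design/noise are shared across discrepancy
values (common random numbers), which reduces Monte-Carlo variance in the
contrasts between discrepancy levels without biasing any mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from .losses import LossFunction, smoothed_huber
from .solvers import StudyData, fit_robust_ridge
from .transfer import (
    DEFAULT_PENALTY_GRID,
    DEFAULT_THETA_GRID,
    CoefficientPair,
    adaptive_trans_rr,
    cv_tune_penalty,
    pooled_rr,
    single_rr,
    trans_rr,
)

__all__ = [
    "DEFAULT_CD_VALUES",
    "SimulatedStudy",
    "ValidityResult",
    "gen_coefficients",
    "gen_study",
    "run_validity_experiment",
    "run_comparison_experiment",
]

DEFAULT_CD_VALUES = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0)

_CASES = ("I", "II", "III")


@dataclass
class SimulatedStudy:
    """Generated study plus the latent noise used to build it."""

    data: StudyData
    eps: np.ndarray
    lam: np.ndarray


def gen_coefficients(
    scheme: str,
    p: int,
    n: int,
    cd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> CoefficientPair:
    """Draw a fixed (target, source) coefficient pair.

    ``diffuse``: entries of ``beta*`` and ``w*`` i.i.d. Unif(0, 1), scaled
    by ``1/sqrt(n)``.  ``normalized``: ``beta0 = beta*/||beta*||`` (unit norm)
    and ``w0 = beta0 - exp(cd) 1_p / sqrt(p)`` so that ``h = exp(cd)``.
    """
    rng = np.random.default_rng(rng)
    if scheme == "diffuse":
        root_n = np.sqrt(n)
        beta0 = rng.uniform(0.0, 1.0, size=p) / root_n
        w0 = rng.uniform(0.0, 1.0, size=p) / root_n
    elif scheme == "normalized":
        beta_star = rng.uniform(0.0, 1.0, size=p)
        beta0 = beta_star / np.linalg.norm(beta_star)
        delta0 = np.exp(cd) * np.ones(p) / np.sqrt(p)
        w0 = beta0 - delta0
    else:
        raise ValueError("scheme must be 'diffuse' or 'normalized'")
    return CoefficientPair(beta0=beta0, w0=w0)


def _ar1_chol(p: int, rho: float) -> np.ndarray:
    if not -1 < rho < 1:
        raise ValueError("AR(1) correlation must lie in (-1, 1)")
    return cholesky(toeplitz(rho ** np.arange(p)), lower=False)


def _draw_noise(case: str, n: int, role: str, rng: np.random.Generator):
    """Latent (eps, lam) for one study; Case III is half Case I, half II."""
    e_scale = 1.0 if role == "target" else 2.0
    if case == "I":
        lam = np.ones(n)
        eps = e_scale * rng.standard_normal(n)
    elif case == "II":
        lam = rng.uniform(0.0, np.sqrt(3.0), size=n)
        eps = e_scale * rng.standard_cauchy(n)
    elif case == "III":
        n1 = (n + 1) // 2
        lam = np.concatenate([np.ones(n1), rng.uniform(0.0, np.sqrt(3.0), size=n - n1)])
        eps = e_scale * np.concatenate(
            [rng.standard_normal(n1), rng.standard_cauchy(n - n1)]
        )
    else:
        raise ValueError(f"case must be one of {_CASES}")
    return eps, lam


def gen_study(
    case: str,
    p: int,
    n: int,
    role: str,
    coef: np.ndarray,
    rng: np.random.Generator | int | None = None,
    covariance="identity",
) -> SimulatedStudy:
    """Generate one study: ``x_i = lam_i X_i`` and ``y = X coef + eps``.

    ``covariance`` is ``"identity"`` or ``("ar1", rho)``, the latter giving
    rows ``X_i ~ N(0, Sigma)`` with ``Sigma_jk = rho^|j-k|``.
    """
    if role not in ("target", "source"):
        raise ValueError("role must be 'target' or 'source'")
    rng = np.random.default_rng(rng)
    coef = np.asarray(coef, dtype=float)
    if coef.shape != (p,):
        raise ValueError("coef length must equal p")
    Z = rng.standard_normal((n, p))
    if covariance != "identity":
        kind, rho = covariance
        if kind != "ar1":
            raise ValueError("covariance must be 'identity' or ('ar1', rho)")
        Z = Z @ _ar1_chol(p, rho)
    eps, lam = _draw_noise(case, n, role, rng)
    X = lam[:, None] * Z
    y = X @ coef + eps
    return SimulatedStudy(data=StudyData(X, y), eps=eps, lam=lam)


@dataclass
class ValidityResult:
    """Replicate-level squared errors and the matching theory solution."""

    case: str
    p: int
    n: int
    n1: int
    tau: float
    tau1: float
    n_reps: int
    errors_sq: np.ndarray = field(repr=False)
    discrepancies: np.ndarray = field(repr=False)
    coefficients: CoefficientPair = field(repr=False, default=None)
    r2_theory: float | None = None
    c_theory: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors_sq))

    @property
    def sd(self) -> float:
        if self.n_reps < 2:
            return float("nan")
        return float(np.std(self.errors_sq, ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n_reps)

    @property
    def mean_discrepancy(self) -> float:
        return float(np.mean(self.discrepancies))

    def summary(self) -> dict:
        return {
            "case": self.case,
            "p": self.p,
            "n": self.n,
            "n1": self.n1,
            "n_reps": self.n_reps,
            "mean_err_sq": self.mean,
            "sd_err_sq": self.sd,
            "mean_discrepancy": self.mean_discrepancy,
            "r2_theory": self.r2_theory,
        }


def run_validity_experiment(
    case: str,
    p: int,
    n: int,
    n1: int,
    n_reps: int = 200,
    seed: int = 0,
    loss: LossFunction | None = None,
    tau: float = 1.0,
    tau1: float = 1.0,
    solve_theory: bool = True,
) -> ValidityResult:
    """Monte-Carlo check of the asymptotic-risk solver.

    Diffuse coefficients are fixed once; each replicate regenerates both
    studies, runs the two-stage estimator at fixed penalties with the
    smoothed Huber loss in both stages, and records the squared l2 error
    and the realized discrepancy ``||beta0 - w_hat||``.  With
    ``solve_theory`` the risk system is solved at ``kappa = p/n`` and the
    replicate-averaged realized discrepancy, giving the predicted squared
    error ``r^2`` for comparison with the empirical mean.
    """
    from .theory import case_mixture, solve_risk_system

    loss = loss or smoothed_huber()
    ss = np.random.SeedSequence(seed)
    coef_ss, data_ss = ss.spawn(2)
    coefs = gen_coefficients("diffuse", p, n, rng=np.random.default_rng(coef_ss))

    errors = np.empty(n_reps)
    discrepancies = np.empty(n_reps)
    for rep, rep_ss in enumerate(data_ss.spawn(n_reps)):
        rng = np.random.default_rng(rep_ss)
        source = gen_study(case, p, n1, "source", coefs.w0, rng)
        target = gen_study(case, p, n, "target", coefs.beta0, rng)
        fit = trans_rr(target.data, source.data, loss, loss, tau=tau, tau1=tau1)
        errors[rep] = np.sum((fit.beta_hat - coefs.beta0) ** 2)
        discrepancies[rep] = np.linalg.norm(coefs.beta0 - fit.w_hat)

    result = ValidityResult(
        case=case,
        p=p,
        n=n,
        n1=n1,
        tau=tau,
        tau1=tau1,
        n_reps=n_reps,
        errors_sq=errors,
        discrepancies=discrepancies,
        coefficients=coefs,
    )
    if solve_theory:
        sol = solve_risk_system(
            loss,
            kappa=p / n,
            tau=tau,
            spec=case_mixture(case, "target"),
            d=result.mean_discrepancy,
        )
        result.r2_theory = sol.r ** 2
        result.c_theory = sol.c
    return result


def _resolve_methods(methods):
    valid = ("single", "trans", "ada", "pooled")
    methods = tuple(methods)
    for m in methods:
        if m not in valid:
            raise ValueError(f"unknown method {m!r}; expected subset of {valid}")
    return methods


def run_comparison_experiment(
    case: str = "I",
    p: int = 400,
    n: int | None = None,
    n1: int | None = None,
    cd_values=DEFAULT_CD_VALUES,
    methods=("single", "trans", "ada", "pooled"),
    tuning: str = "cv_mae",
    fixed_tau: float = 1.0,
    n_reps: int = 50,
    seed: int = 0,
    K: int = 5,
    grid=DEFAULT_PENALTY_GRID,
    theta_grid=DEFAULT_THETA_GRID,
    covariance="identity",
    loss: LossFunction | None = None,
):
    """Sweep the source-target discrepancy and compare estimators.

    ``tuning`` is ``"cv_mae"`` or ``"cv_mse"`` (each ridge penalty tuned by
    K-fold cross-validation under that criterion, and the adaptive
    mixing-weight validation loss switched to match) or ``"fixed"`` (all
    penalties forced to ``fixed_tau``; the mixing weight is still
    cross-validated).  Returns ``(summary, per_rep)`` data frames; the
    summary reports, per (h, method), the mean relative squared error
    ``||est - beta0||^2 / ||beta0||^2`` together with the absolute error
    and its standard error.
    """
    n = n or p
    n1 = n1 or 2 * p
    methods = _resolve_methods(methods)
    loss = loss or smoothed_huber()
    if tuning in ("cv_mae", "cv_mse"):
        criterion = "mae" if tuning == "cv_mae" else "mse"
        use_cv = True
    elif tuning == "fixed":
        criterion = "mae"
        use_cv = False
    else:
        raise ValueError("tuning must be 'cv_mae', 'cv_mse', or 'fixed'")

    ss = np.random.SeedSequence(seed)
    coef_ss, data_ss, tune_ss, theta_ss = ss.spawn(4)
    beta_pair = gen_coefficients(
        "normalized", p, n, cd=0.0, rng=np.random.default_rng(coef_ss)
    )
    beta0 = beta_pair.beta0
    beta0_sq = float(np.sum(beta0**2))
    cd_values = tuple(float(c) for c in cd_values)
    w0_by_cd = {
        cd: beta0 - np.exp(cd) * np.ones(p) / np.sqrt(p) for cd in cd_values
    }

    rep_data = data_ss.spawn(n_reps)
    rep_tune = tune_ss.spawn(n_reps)
    rep_theta = theta_ss.spawn(n_reps)
    records = []
    for rep in range(n_reps):
        rng = np.random.default_rng(rep_data[rep])
        tune_rng = np.random.default_rng(rep_tune[rep])
        theta_rng = np.random.default_rng(rep_theta[rep])

        target = gen_study(case, p, n, "target", beta0, rng, covariance)
        # source design and noise are shared across cd; only y changes
        src = gen_study(case, p, n1, "source", np.zeros(p), rng, covariance)

        need_single = "single" in methods or "ada" in methods
        single_fit = None
        if need_single:
            if use_cv:
                tau_st = cv_tune_penalty(
                    target.data, loss, grid, K=K, criterion=criterion,
                    rng=tune_rng,
                )
            else:
                tau_st = fixed_tau
            single_fit = single_rr(target.data, loss, tau_st)

        for cd in cd_values:
            w0 = w0_by_cd[cd]
            h = float(np.exp(cd))
            source_data = StudyData(src.data.X, src.data.X @ w0 + src.eps)

            def record(method, coef, extra=None):
                err = float(np.sum((coef - beta0) ** 2))
                rec = {
                    "rep": rep,
                    "case": case,
                    "cd": cd,
                    "h": h,
                    "method": method,
                    "err_sq": err,
                    "rel_err": err / beta0_sq,
                }
                if extra:
                    rec.update(extra)
                records.append(rec)

            if need_single:
                record("single", single_fit.coef, {"tau_st": single_fit.tau})

            transfer_fit = None
            if "trans" in methods or "ada" in methods:
                if use_cv:
                    tau1 = cv_tune_penalty(
                        source_data, loss, grid, K=K, criterion=criterion,
                        rng=tune_rng,
                    )
                    w_fit = fit_robust_ridge(source_data, loss, tau1)
                    offset = target.data.X @ w_fit.coef
                    tau_t = cv_tune_penalty(
                        target.data, loss, grid, K=K, criterion=criterion,
                        offset=offset, rng=tune_rng,
                    )
                    transfer_fit = trans_rr(
                        target.data, source_data, loss, loss,
                        tau=tau_t, tau1=tau1, w_hat=w_fit.coef,
                    )
                else:
                    transfer_fit = trans_rr(
                        target.data, source_data, loss, loss,
                        tau=fixed_tau, tau1=fixed_tau,
                    )
                if "trans" in methods:
                    record(
                        "trans", transfer_fit.beta_hat,
                        {"tau1": transfer_fit.tau1, "tau": transfer_fit.tau},
                    )

            if "ada" in methods:
                ada = adaptive_trans_rr(
                    target.data, source_data, loss,
                    tau1=transfer_fit.tau1, tau=transfer_fit.tau,
                    tau_st=single_fit.tau, K=K, theta_grid=theta_grid,
                    criterion=criterion, rng=theta_rng,
                    transfer_fit=transfer_fit, single_fit=single_fit,
                )
                record("ada", ada.beta_ada, {"theta_hat": ada.theta_hat})

            if "pooled" in methods:
                if use_cv:
                    pooled_data = StudyData(
                        np.vstack([target.data.X, source_data.X]),
                        np.concatenate([target.data.y, source_data.y]),
                    )
                    tau_p = cv_tune_penalty(
                        pooled_data, loss, grid, K=K, criterion=criterion,
                        rng=tune_rng,
                    )
                else:
                    tau_p = fixed_tau
                pooled_fit = pooled_rr(target.data, source_data, loss, tau_p)
                record("pooled", pooled_fit.coef, {"tau_p": pooled_fit.tau})

    per_rep = pd.DataFrame.from_records(records)
    summary = (
        per_rep.groupby(["case", "cd", "h", "method"], as_index=False)
        .agg(
            mean_rel_err=("rel_err", "mean"),
            mean_err_sq=("err_sq", "mean"),
            se_rel_err=("rel_err", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
            n_reps=("rel_err", "size"),
        )
        .sort_values(["case", "h", "method"])
        .reset_index(drop=True)
    )
    return summary, per_rep
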