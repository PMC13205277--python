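"""Two-stage transfer estimator, baselines, penalty tuning, and the
adaptive anti-negative-transfer aggregation.

The transfer estimator fits a robust ridge regression on the source study
(coefficients ``w_hat``), then fits a robust ridge *correction*
``delta_hat`` on the target study against the offset ``X @ w_hat``, and
returns ``beta_hat = w_hat + delta_hat``.  Because the correction is
shrunk toward zero, the estimator inherits accuracy from the source when
the studies are similar but degrades when the source-target coefficient
discrepancy is large (negative transfer).  The adaptive variant mixes the
transfer fit with the single-study fit, ``theta * beta_hat + (1 - theta) *
beta_st``, choosing ``theta`` by K-fold cross-validation on the target
study so the procedure can fall back to either endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import LossFunction
from .solvers import RidgeFit, StudyData, fit_robust_ridge

__all__ = [
    "DEFAULT_PENALTY_GRID",
    "DEFAULT_THETA_GRID",
    "CoefficientPair",
    "TransferFit",
    "AdaptiveFit",
    "trans_rr",
    "single_rr",
    "pooled_rr",
    "cv_tune_penalty",
    "adaptive_trans_rr",
]

# geometric grid 3^a, a = -2, -1.5, ..., 2 (9 points spanning [1/9, 9])
DEFAULT_PENALTY_GRID = tuple(float(3.0**a) for a in np.arange(-2.0, 2.01, 0.5))
DEFAULT_THETA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class CoefficientPair:
    """Ground-truth target/source coefficients and their discrepancy."""

    beta0: np.ndarray
    w0: np.ndarray

    @property
    def delta0(self) -> np.ndarray:
        return self.beta0 - self.w0

    @property
    def h(self) -> float:
        return float(np.linalg.norm(self.delta0))


@dataclass
class TransferFit:
    """Source-stage fit, target-stage correction, and their sum."""

    w_hat: np.ndarray
    delta_hat: np.ndarray
    tau1: float
    tau: float
    source_fit: RidgeFit = field(repr=False, default=None)
    target_fit: RidgeFit = field(repr=False, default=None)

    @property
    def beta_hat(self) -> np.ndarray:
        return self.w_hat + self.delta_hat

    def to_dict(self) -> dict:
        return {
            "w_hat": self.w_hat.tolist(),
            "delta_hat": self.delta_hat.tolist(),
            "beta_hat": self.beta_hat.tolist(),
            "tau1": self.tau1,
            "tau": self.tau,
        }


@dataclass
class AdaptiveFit:
    """Cross-validated convex combination of transfer and single fits."""

    theta_hat: float
    beta_ada: np.ndarray
    theta_grid: tuple
    K: int
    cv_losses: dict
    transfer_fit: TransferFit = field(repr=False, default=None)
    single_fit: RidgeFit = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat,
            "beta_ada": self.beta_ada.tolist(),
            "theta_grid": list(self.theta_grid),
            "K": self.K,
            "cv_losses": {str(k): v for k, v in self.cv_losses.items()},
        }


def trans_rr(
    target: StudyData,
    source: StudyData,
    loss_target: LossFunction,
    loss_source: LossFunction,
    tau: float,
    tau1: float,
    w_hat: np.ndarray | None = None,
    x0_delta: np.ndarray | None = None,
) -> TransferFit:
    """Two-stage transfer estimator.

    Stage 1 fits ``w_hat`` on the source study with penalty ``tau1``;
    stage 2 fits the correction ``delta_hat`` on the target study with
    offset ``target.X @ w_hat`` and penalty ``tau``.  A precomputed
    ``w_hat`` may be passed to skip stage 1 (used when refitting on
    target subsets with the full-source stage-1 fit held fixed).
    """
    if target.p != source.p:
        raise ValueError("target and source must have the same number of predictors")
    if w_hat is None:
        source_fit = fit_robust_ridge(source, loss_source, tau1)
        w_hat = source_fit.coef
    else:
        source_fit = None
        w_hat = np.asarray(w_hat, dtype=float)
    offset = target.X @ w_hat
    target_fit = fit_robust_ridge(target, loss_target, tau, offset=offset, x0=x0_delta)
    return TransferFit(
        w_hat=w_hat,
        delta_hat=target_fit.coef,
        tau1=float(tau1),
        tau=float(tau),
        source_fit=source_fit,
        target_fit=target_fit,
    )


def single_rr(target: StudyData, loss: LossFunction, tau_st: float) -> RidgeFit:
    """Single-study robust ridge fit on the target sample alone."""
    return fit_robust_ridge(target, loss, tau_st)


def pooled_rr(
    target: StudyData, source: StudyData, loss: LossFunction, tau_p: float
) -> RidgeFit:
    """Robust ridge fit on the row-concatenated source + target sample."""
    if target.p != source.p:
        raise ValueError("target and source must have the same number of predictors")
    pooled = StudyData(
        np.vstack([target.X, source.X]), np.concatenate([target.y, source.y])
    )
    return fit_robust_ridge(pooled, loss, tau_p)


def _kfold_indices(n: int, K: int, rng: np.random.Generator):
    """Random permutation split into K near-equal blocks of indices."""
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, K)]


def _validation_loss(resid: np.ndarray, criterion: str) -> float:
    if criterion == "mae":
        return float(np.sum(np.abs(resid)))
    if criterion == "mse":
        return float(np.sum(resid**2))
    raise ValueError(f"unknown criterion {criterion!r}")


def cv_tune_penalty(
    data: StudyData,
    loss: LossFunction,
    grid=DEFAULT_PENALTY_GRID,
    K: int = 5,
    criterion: str = "mae",
    offset: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Select the ridge penalty by K-fold cross-validation.

    Out-of-fold residuals are scored by mean absolute error (default) or
    mean squared error; ties in the aggregated score break toward the
    smallest grid value.  Within each fold the grid is swept from the
    largest penalty down, warm-starting each fit at the previous solution.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("penalty grid must be non-empty")
    if any(g <= 0 for g in grid):
        raise ValueError("penalties must be positive")
    if K < 2:
        raise ValueError("K must be at least 2")
    if data.n < K:
        raise ValueError("need at least K observations")
    rng = np.random.default_rng(rng)
    folds = _kfold_indices(data.n, K, rng)
    offset = np.zeros(data.n) if offset is None else np.asarray(offset, dtype=float)

    totals = {g: 0.0 for g in grid}
    all_idx = np.arange(data.n)
    for val_idx in folds:
        train_mask = np.ones(data.n, dtype=bool)
        train_mask[val_idx] = False
        train_idx = all_idx[train_mask]
        train = data.subset(train_idx)
        coef = None
        for g in reversed(grid):
            fit = fit_robust_ridge(
                train, loss, g, offset=offset[train_idx], x0=coef
            )
            coef = fit.coef
            resid = data.y[val_idx] - offset[val_idx] - data.X[val_idx] @ coef
            totals[g] += _validation_loss(resid, criterion)

    best = grid[0]
    best_loss = totals[best]
    for g in grid[1:]:
        if totals[g] < best_loss:
            best, best_loss = g, totals[g]
    return best


def adaptive_trans_rr(
    target: StudyData,
    source: StudyData,
    loss: LossFunction,
    tau1: float,
    tau: float,
    tau_st: float,
    K: int = 5,
    theta_grid=DEFAULT_THETA_GRID,
    criterion: str = "mae",
    rng: np.random.Generator | int | None = None,
    transfer_fit: TransferFit | None = None,
    single_fit: RidgeFit | None = None,
) -> AdaptiveFit:
    """Adaptive aggregation of the transfer and single-study estimators.

    The penalties are assumed already tuned and are reused across all K
    folds.  A fresh K-fold partition of the target sample (independent of
    any tuning partitions: pass an independent ``rng`` stream) drives the
    selection of the mixing weight ``theta``: each fold refits the
    transfer correction and the single-study estimator on the remaining
    target data, and the pooled out-of-fold loss of the mixed predictor is
    minimized over ``theta_grid``.  Ties break toward the smallest
    ``theta`` (prefer the single-study fallback).
    """
    theta_grid = tuple(float(t) for t in theta_grid)
    if not (0.0 in theta_grid and 1.0 in theta_grid):
        raise ValueError("theta_grid must contain both endpoints 0 and 1")
    if any(t < 0 or t > 1 for t in theta_grid):
        raise ValueError("theta values must lie in [0, 1]")
    if K < 2:
        raise ValueError("K must be at least 2")
    if target.n < K:
        raise ValueError("need at least K target observations")
    rng = np.random.default_rng(rng)

    if transfer_fit is None:
        transfer_fit = trans_rr(target, source, loss, loss, tau=tau, tau1=tau1)
    if single_fit is None:
        single_fit = single_rr(target, loss, tau_st)
    w_hat = transfer_fit.w_hat

    folds = _kfold_indices(target.n, K, rng)
    all_idx = np.arange(target.n)
    totals = {t: 0.0 for t in theta_grid}
    for val_idx in folds:
        train_mask = np.ones(target.n, dtype=bool)
        train_mask[val_idx] = False
        train = target.subset(all_idx[train_mask])
        # stage 1 uses the full source sample, so w_hat is fold-independent
        fold_transfer = trans_rr(
            train, source, loss, loss, tau=tau, tau1=tau1,
            w_hat=w_hat, x0_delta=transfer_fit.delta_hat,
        )
        fold_single = fit_robust_ridge(
            train, loss, tau_st, x0=single_fit.coef
        )
        pred_transfer = target.X[val_idx] @ fold_transfer.beta_hat
        pred_single = target.X[val_idx] @ fold_single.coef
        y_val = target.y[val_idx]
        for t in theta_grid:
            resid = y_val - (t * pred_transfer + (1.0 - t) * pred_single)
            totals[t] += _validation_loss(resid, criterion)

    order = sorted(theta_grid)
    theta_hat = order[0]
    best = totals[theta_hat]
    for t in order[1:]:
        if totals[t] < best:
            theta_hat, best = t, totals[t]

    beta_ada = theta_hat * transfer_fit.beta_hat + (1.0 - theta_hat) * single_fit.coef
    n = target.n
    return AdaptiveFit(
        theta_hat=theta_hat,
        beta_ada=beta_ada,
        theta_grid=theta_grid,
        K=K,
        cv_losses={t: totals[t] / n for t in theta_grid},
        transfer_fit=transfer_fit,
        single_fit=single_fit,
    )
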