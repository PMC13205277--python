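"""Spectral-style preprocessing: wavelength thinning, whitening, metrics.

For calibration-transfer-style data, adjacent spectral channels are highly
collinear; the pipeline thins columns (keep every ``step``-th wavelength)
and then whitens the predictors, ``X_tilde = (X - mu_hat) Sigma_hat^{-1/2}``,
so the sample second-moment matrix approximates the identity — the design
geometry assumed by the asymptotic theory.  All transform parameters are
estimated on training data only and applied unchanged to test data.

With n at or below p the sample covariance is singular; the inverse square
root is formed by eigen-decomposition with a pseudo-inverse on eigenvalues
above ``1e-10`` times the largest, and an optional ridge-regularized
variant ``(Sigma_hat + gamma I)^{-1/2}`` is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PreprocessModel", "thin_columns", "fit_whitener", "apply_whitener", "rmse"]


def thin_columns(X: np.ndarray, step: int, offset: int = 1) -> np.ndarray:
    """Keep columns ``offset, offset + step, ...`` (1-based offset)."""
    if step < 1:
        raise ValueError("step must be at least 1")
    if not 1 <= offset <= step:
        raise ValueError("offset must lie in [1, step]")
    X = np.asarray(X)
    return X[:, offset - 1 :: step]


@dataclass
class PreprocessModel:
    """Whitening transform estimated from one training sample."""

    mu_hat: np.ndarray
    whitener: np.ndarray  # symmetric PSD root of the (pseudo-)inverse covariance
    y_center: float = 0.0
    keep_indices: np.ndarray | None = None
    rank: int | None = None


def fit_whitener(
    X_train: np.ndarray,
    y_train: np.ndarray | None = None,
    ridge_gamma: float | None = None,
    rel_tol: float = 1e-10,
) -> PreprocessModel:
    """Estimate the centering/whitening transform from training data.

    The covariance ``Sigma_hat = X_c' X_c / n`` (centered, divisor ``n``)
    is eigen-decomposed; eigenvalues at or below ``rel_tol`` times the
    largest are treated as null directions and pseudo-inverted to zero.
    With ``ridge_gamma`` set, ``(Sigma_hat + gamma I)^{-1/2}`` is used
    instead (full rank).  ``y_train``, if given, provides the response
    centering constant.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 1:
        raise ValueError("X_train must be a nonempty 2-d array")
    mu = X_train.mean(axis=0)
    Xc = X_train - mu
    n = X_train.shape[0]
    cov = Xc.T @ Xc / n
    if ridge_gamma is not None:
        if ridge_gamma <= 0:
            raise ValueError("ridge_gamma must be positive")
        cov = cov + ridge_gamma * np.eye(cov.shape[0])
    evals, evecs = np.linalg.eigh(cov)
    top = evals[-1]
    if top <= 0:
        raise ValueError("degenerate training sample: zero covariance")
    keep = evals > rel_tol * top
    inv_root = np.zeros_like(evals)
    inv_root[keep] = evals[keep] ** -0.5
    whitener = (evecs * inv_root) @ evecs.T
    y_center = float(np.mean(y_train)) if y_train is not None else 0.0
    return PreprocessModel(
        mu_hat=mu, whitener=whitener, y_center=y_center, rank=int(keep.sum())
    )


def apply_whitener(model: PreprocessModel, X: np.ndarray) -> np.ndarray:
    """Apply a trained centering/whitening transform to new data."""
    X = np.asarray(X, dtype=float)
    return (X - model.mu_hat) @ model.whitener


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared prediction error on the original response scale."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))
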