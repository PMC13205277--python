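"""Proximal mapping of ``c * rho`` and its derivative.

For a differentiable convex loss ``rho`` with score ``psi``, the proximal
mapping ``prox(c rho)(x) = argmin_y c rho(y) + (x - y)^2 / 2`` is the unique
root of ``y + c psi(y) = x``, and its derivative in ``x`` is
``1 / (1 + c psi'(y))``.  This scalar map is the computational kernel of the
asymptotic-risk system, so evaluation must be fast over large quadrature
grids: the smoothed Huber, Huber, and quadratic losses use exact piecewise
solutions; other losses fall back to a safeguarded elementwise Newton
iteration bracketed by ``[x - c psi_sup, x + c psi_sup]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import LossFunction

__all__ = ["ProxResult", "prox_eval", "prox_value", "prox_derivative"]

_RESID_TOL = 1e-12
_MAX_NEWTON = 200


@dataclass(frozen=True)
class ProxResult:
    """Value and derivative of the proximal map at one point."""

    value: float
    derivative: float
    scale: float


def _prox_smoothed_huber(loss: LossFunction, c, x):
    """Closed-form prox for the smoothed Huber loss (three branches)."""
    d, e = loss.delta, loss.eta
    c = np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    s = np.sign(x)
    y_inner = x / (1.0 + c)  # valid while |y| <= d - e
    y_outer = x - c * s * (d - e / 2.0)  # valid while |y| >= d
    # middle band: y = s (d - t) with (c/(2e)) t^2 + t - A = 0, t in [0, e]
    amount = d + c * (d - e / 2.0) - a
    amount = np.maximum(amount, 0.0)
    t = 2.0 * amount / (1.0 + np.sqrt(1.0 + 2.0 * c * amount / e))
    y_mid = s * (d - t)
    inner = a <= (1.0 + c) * (d - e)
    outer = a >= d + c * (d - e / 2.0)
    return np.where(inner, y_inner, np.where(outer, y_outer, y_mid))


def _prox_huber(loss: LossFunction, c, x):
    d = loss.delta
    c = np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    y_inner = x / (1.0 + c)
    y_outer = x - c * d * np.sign(x)
    return np.where(np.abs(x) <= (1.0 + c) * d, y_inner, y_outer)


def _prox_generic(loss: LossFunction, c, x):
    """Safeguarded elementwise Newton on ``f(y) = y + c psi(y) - x``.

    ``f`` is strictly increasing with ``f' >= 1``, so Newton from any point
    inside the bracket converges; iterates are clipped to the bracket and a
    bisection step replaces any Newton step that leaves it.
    """
    c = np.broadcast_to(np.asarray(c, dtype=float), np.broadcast(c, x).shape).copy()
    x = np.broadcast_to(np.asarray(x, dtype=float), c.shape).copy()
    span = c * min(loss.psi_sup, 1e10)
    lo = x - span
    hi = x + span
    y = x / (1.0 + c)  # exact for quadratic, decent generally
    scale = np.maximum(1.0, np.abs(x))
    for _ in range(_MAX_NEWTON):
        f = y + c * loss.psi(y) - x
        done = np.abs(f) <= _RESID_TOL * scale
        if done.all():
            break
        lo = np.where(f < 0, y, lo)
        hi = np.where(f > 0, y, hi)
        step = f / (1.0 + c * loss.psi_prime(y))
        y_new = y - step
        bad = (y_new <= lo) | (y_new >= hi)
        y = np.where(done, y, np.where(bad, 0.5 * (lo + hi), y_new))
    return y


def prox_value(loss: LossFunction, c, x):
    """Vectorized ``prox(c rho)(x)``; ``c`` may broadcast against ``x``."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ValueError("prox scale c must be strictly positive")
    if loss.name == "smoothed_huber":
        out = _prox_smoothed_huber(loss, c_arr, x)
    elif loss.name == "huber":
        out = _prox_huber(loss, c_arr, x)
    elif loss.name == "quadratic":
        out = np.asarray(x, dtype=float) / (1.0 + c_arr)
    else:
        out = _prox_generic(loss, c_arr, x)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def prox_derivative(loss: LossFunction, c, y):
    """Derivative ``1 / (1 + c psi'(y))`` evaluated at ``y = prox(x)``."""
    return 1.0 / (1.0 + np.asarray(c, dtype=float) * loss.psi_prime(y))


def prox_eval(loss: LossFunction, c: float, x: float) -> ProxResult:
    """Evaluate the proximal map of ``c * rho`` at scalar ``x``.

    Returns the minimizer ``y`` of ``c rho(y) + (x - y)^2 / 2`` together
    with its derivative in ``x``; raises for non-positive ``c``.
    """
    if not c > 0:
        raise ValueError("prox scale c must be strictly positive")
    y = float(np.asarray(prox_value(loss, c, x)))
    return ProxResult(value=y, derivative=float(prox_derivative(loss, c, y)), scale=float(c))
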