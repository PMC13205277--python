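"""Robust loss family for ridge-regularized M-estimation.

The workhorse is the smoothed Huber loss: a Huber loss whose corner at
``|x| = delta`` is replaced by a cubic blend on ``(delta - eta, delta)`` so
that the score ``psi = rho'`` has a Lipschitz, bounded derivative.  The
pseudo-Huber loss is a fully smooth alternative with the same bounded-score
behaviour.  The unsmoothed Huber loss is kept for reference (its ``psi'`` is
discontinuous, so the asymptotic-risk solver refuses it), and the quadratic
loss is kept as a closed-form testing oracle (unbounded score).

All evaluators accept scalars or ndarrays and broadcast elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossFunction",
    "smoothed_huber",
    "pseudo_huber",
    "huber",
    "quadratic",
]

_NAMES = ("smoothed_huber", "pseudo_huber", "huber", "quadratic")


@dataclass(frozen=True)
class LossFunction:
    """An even, convex robust loss ``rho`` with score ``psi`` and ``psi'``.

    Parameters
    ----------
    name:
        One of ``smoothed_huber``, ``pseudo_huber``, ``huber``, ``quadratic``.
    delta:
        Huber threshold; the loss grows linearly (or asymptotically
        linearly) beyond roughly this scale.  Ignored by ``quadratic``.
    eta:
        Smoothing width of the cubic blend, meaningful only for
        ``smoothed_huber``; must satisfy ``0 < eta < delta``.
    """

    name: str
    delta: float = 1.35
    eta: float = 0.1

    def __post_init__(self) -> None:
        if self.name not in _NAMES:
            raise ValueError(f"unknown loss {self.name!r}; expected one of {_NAMES}")
        if self.name in ("smoothed_huber", "pseudo_huber", "huber"):
            if not self.delta > 0:
                raise ValueError("delta must be positive")
        if self.name == "smoothed_huber":
            if not (0 < self.eta < self.delta):
                raise ValueError("smoothed Huber requires 0 < eta < delta")

    @property
    def psi_sup(self) -> float:
        """Supremum of ``|psi|`` (``inf`` for the quadratic loss)."""
        if self.name == "smoothed_huber":
            return self.delta - self.eta / 2.0
        if self.name in ("pseudo_huber", "huber"):
            return self.delta
        return np.inf

    @property
    def is_smooth(self) -> bool:
        """Whether ``psi'`` is continuous (required by the risk solver)."""
        return self.name in ("smoothed_huber", "pseudo_huber", "quadratic")

    # -- loss value -------------------------------------------------------

    def rho(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "quadratic":
            out = 0.5 * x * x
        elif self.name == "pseudo_huber":
            d = self.delta
            out = d * d * (np.sqrt(1.0 + (x / d) ** 2) - 1.0)
        elif self.name == "huber":
            d = self.delta
            a = np.abs(x)
            out = np.where(a <= d, 0.5 * a * a, d * a - 0.5 * d * d)
        else:  # smoothed_huber
            d, e = self.delta, self.eta
            c_rho = -e * e / 6.0 + e * d / 2.0 - d * d / 2.0
            a = np.abs(x)
            lin = (d - e / 2.0) * a + c_rho
            mid = lin + (d - a) ** 3 / (6.0 * e)
            # ties at |x| = d - e belong to the closed quadratic branch
            out = np.where(a <= d - e, 0.5 * a * a, np.where(a < d, mid, lin))
        return out if out.ndim else float(out)

    # -- score ------------------------------------------------------------

    def psi(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "quadratic":
            out = x.copy()
        elif self.name == "pseudo_huber":
            out = x / np.sqrt(1.0 + (x / self.delta) ** 2)
        elif self.name == "huber":
            out = np.clip(x, -self.delta, self.delta)
        else:
            d, e = self.delta, self.eta
            a = np.abs(x)
            s = np.sign(x)
            mid = s * ((d - e / 2.0) - (d - a) ** 2 / (2.0 * e))
            out = np.where(a <= d - e, x, np.where(a < d, mid, s * (d - e / 2.0)))
        return out if out.ndim else float(out)

    # -- score derivative --------------------------------------------------

    def psi_prime(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "quadratic":
            out = np.ones_like(x)
        elif self.name == "pseudo_huber":
            out = (1.0 + (x / self.delta) ** 2) ** -1.5
        elif self.name == "huber":
            out = np.where(np.abs(x) <= self.delta, 1.0, 0.0)
        else:
            d, e = self.delta, self.eta
            a = np.abs(x)
            out = np.where(a <= d - e, 1.0, np.where(a < d, (d - a) / e, 0.0))
        return out if out.ndim else float(out)


def smoothed_huber(delta: float = 1.35, eta: float = 0.1) -> LossFunction:
    """Smoothed Huber loss; the default everywhere in this package."""
    return LossFunction("smoothed_huber", delta=delta, eta=eta)


def pseudo_huber(delta: float = 1.35) -> LossFunction:
    return LossFunction("pseudo_huber", delta=delta)


def huber(delta: float = 1.35) -> LossFunction:
    """Unsmoothed Huber loss (reference only; ``psi'`` has jumps)."""
    return LossFunction("huber", delta=delta)


def quadratic() -> LossFunction:
    """Squared-error loss ``x^2/2``; testing oracle with closed-form ridge."""
    return LossFunction("quadratic")
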