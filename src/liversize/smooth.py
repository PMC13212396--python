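"""Penalized B-spline (P-spline) basis utilities.

A basis of cubic B-splines on equally spaced knots spanning the training
covariate range, with a difference penalty on adjacent coefficients. With
``n_knots`` equal-width spans and degree ``d`` the basis has
``n_knots + d`` functions (knots at the span boundaries, boundary knots
repeated ``d + 1`` times).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SmoothConfig", "BSplineBasis", "difference_penalty"]


@dataclass(frozen=True)
class SmoothConfig:
    """Smoothing configuration for the three smooth BCPE predictors.

    ``lam`` entries may be positive floats (fixed lambda), ``"light"``
    (fixed light relative ridge, the default) or ``"gaic"`` (GAIC grid
    search; see the fitter). ``x_power`` applies a monotone power transform
    to the covariate before the basis is built (0.5 compresses the upper
    age range so the rapid infant rise gets proportionally more knots;
    1 = identity).
    """

    n_knots: int = 12
    degree: int = 3
    penalty_order: int = 2
    lam_mu: float | str = "light"
    lam_sigma: float | str = "light"
    lam_nu: float | str = "light"
    link_mu: str = "log"
    link_sigma: str = "log"
    link_nu: str = "identity"
    link_tau: str = "log"
    x_power: float = 1.0

    def __post_init__(self):
        if self.n_knots < self.penalty_order + 1:
            raise ValueError("n_knots must be >= penalty_order + 1")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if not (0 < self.x_power <= 2):
            raise ValueError("x_power must be in (0, 2]")


def difference_penalty(n_basis: int, order: int) -> np.ndarray:
    """Penalty matrix D'D for the given difference order."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass(frozen=True)
class BSplineBasis:
    """Equally spaced B-spline basis frozen to a training range."""

    lo: float
    hi: float
    n_knots: int
    degree: int

    @property
    def n_basis(self) -> int:
        return self.n_knots + self.degree

    @property
    def knots(self) -> np.ndarray:
        inner = np.linspace(self.lo, self.hi, self.n_knots + 1)
        step = (self.hi - self.lo) / self.n_knots
        left = self.lo + step * np.arange(-self.degree, 0)
        right = self.hi + step * np.arange(1, self.degree + 1)
        return np.concatenate([left, inner, right])

    def design(self, x) -> np.ndarray:
        """Design matrix at ``x``; rows sum to one (partition of unity).

        Raises for values outside the training range: the model refuses
        to extrapolate.
        """
        x = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError("non-finite covariate value")
        if np.any(x < self.lo - 1e-12) or np.any(x > self.hi + 1e-12):
            raise ValueError(
                f"covariate outside the training range [{self.lo:g}, {self.hi:g}]: "
                "extrapolation refused"
            )
        xc = np.clip(x, self.lo, self.hi)
        # uniform knot extension (classic P-spline construction); the knot
        # vector has n_basis + degree + 1 entries and the basis partitions
        # unity exactly on [lo, hi]
        B = BSpline.design_matrix(xc, self.knots, self.degree)
        return B.toarray()
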