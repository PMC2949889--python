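"""Cubic B-spline basis for the transfer functions.

Every pairwise transfer function h^{mk} (the log fold-change a mark-m point
exerts on the intensity of mark k at downstream lag t) is parameterized as
a linear combination of cubic B-spline basis functions on a fixed,
equidistant knot grid:

    h(t) = beta' B(t),   B(t) = (B_1(t), ..., B_d(t)).

The default grid places 8 simple (unrepeated) knots equidistantly on
[-400, 1000] base pairs.  With simple knots and cubic order 4 this yields
exactly ``n_knots - order = 4`` basis functions, so each transfer function
carries 4 free coefficients and the likelihood-ratio test of "no effect"
has 4 degrees of freedom.  The basis -- and hence h -- vanishes identically
beyond the last knot, which caps the range of detectable dependence at
1000 bp downstream.  The grid extends to negative lags only so that h(0)
need not be zero; the model never evaluates h at negative lags because the
intensity integrates over the strict past.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "evaluate_basis", "evaluate_h"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot grid and order defining the transfer-function basis.

    Parameters
    ----------
    first_knot, last_knot : float
        Endpoints of the equidistant knot grid, in base pairs.  The last
        knot is the maximum lag at which dependence can be detected.
    n_knots : int
        Number of knots.  All knots are simple, so the basis dimension is
        ``n_knots - order``.
    order : int
        Spline order (4 = cubic).
    """

    first_knot: float = -400.0
    last_knot: float = 1000.0
    n_knots: int = 8
    order: int = 4

    def __post_init__(self) -> None:
        if self.last_knot <= self.first_knot:
            raise ValueError("last_knot must exceed first_knot")
        if self.n_knots <= self.order:
            raise ValueError("need more knots than the spline order")

    @property
    def knots(self) -> np.ndarray:
        return np.linspace(self.first_knot, self.last_knot, self.n_knots)

    @property
    def n_basis(self) -> int:
        """Dimension of the basis (number of free coefficients per pair)."""
        return self.n_knots - self.order

    @property
    def support(self) -> tuple[float, float]:
        return (self.first_knot, self.last_knot)

    def basis_matrix(self, t) -> np.ndarray:
        """Evaluate all basis functions at lags ``t``.

        Returns an array of shape ``t.shape + (n_basis,)``; rows are zero
        outside ``[first_knot, last_knot]``.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        kn = self.knots
        out = np.zeros(t.shape + (self.n_basis,))
        for l in range(self.n_basis):
            elem = BSpline.basis_element(kn[l : l + self.order + 1], extrapolate=False)
            vals = elem(t)
            out[..., l] = np.nan_to_num(vals, nan=0.0)
        # the rightmost knot itself lies outside the (half-open) support
        out[t >= kn[-1]] = 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "first_knot": self.first_knot,
            "last_knot": self.last_knot,
            "n_knots": self.n_knots,
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(**d)


def evaluate_basis(t, spec: SplineSpec) -> np.ndarray:
    """Vector ``B(t)`` of basis values; zero outside the knot range."""
    return spec.basis_matrix(t)


def evaluate_h(t, beta: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate ``h(t) = beta' B(t)`` at lags ``t``.

    Raises ``ValueError`` on a coefficient vector of the wrong length.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (spec.n_basis,):
        raise ValueError(
            f"beta has length {beta.size}, expected {spec.n_basis}"
        )
    return spec.basis_matrix(t) @ beta
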