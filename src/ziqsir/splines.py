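"""Normalized B-spline bases for the single-index sieve.

The unknown quantile link G_tau is approximated by ``B(u)' theta`` where
``B`` is a normalized (partition-of-unity) B-spline basis of order ``m``
(degree ``m-1``) on a clamped knot vector.  The basis dimension is
``J = n_interior + m``.  Evaluation outside the knot range clamps ``u`` to
the boundary, which keeps iterative refits finite when the index range
shifts between iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


class DegenerateBasisError(ValueError):
    """Raised when the index values cannot support the requested basis."""


@dataclass(frozen=True)
class SplineBasis:
    """A clamped, normalized B-spline basis on ``[a, b]``.

    Parameters
    ----------
    order
        Spline order ``m`` (polynomial degree ``m - 1``); ``m = 4`` is cubic.
    boundary
        Interval endpoints ``(a, b)`` with ``a < b``.
    interior
        Strictly increasing interior knots, all inside ``(a, b)``.
    """

    order: int
    boundary: tuple[float, float]
    interior: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        a, b = self.boundary
        interior = np.asarray(self.interior, dtype=float)
        object.__setattr__(self, "interior", interior)
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if not a < b:
            raise DegenerateBasisError(f"empty interval [{a}, {b}]")
        if interior.size and (
            np.any(np.diff(interior) <= 0)
            or interior[0] <= a
            or interior[-1] >= b
        ):
            raise DegenerateBasisError("interior knots must strictly increase inside (a, b)")

    @property
    def dimension(self) -> int:
        """Number of basis functions, ``J = n_interior + order``."""
        return self.interior.size + self.order

    @property
    def knot_vector(self) -> np.ndarray:
        """Full clamped knot vector with boundary multiplicity ``order``."""
        a, b = self.boundary
        return np.concatenate([np.full(self.order, a), self.interior, np.full(self.order, b)])

    def clamp(self, u: np.ndarray) -> np.ndarray:
        a, b = self.boundary
        return np.clip(np.asarray(u, dtype=float), a, b)


def build_basis(index_values: np.ndarray, n_interior: int, order: int = 4) -> SplineBasis:
    """Build a basis adapted to observed index values.

    Boundary knots sit at the min/max of ``index_values``; interior knots sit
    at ``n_interior`` equally spaced empirical quantiles, so knot spacing
    tracks skewed index distributions.  Quantiles that collide with each
    other or with the boundary are dropped (only possible under heavy ties).
    """
    vals = np.asarray(index_values, dtype=float).ravel()
    if vals.size == 0 or not np.all(np.isfinite(vals)):
        raise DegenerateBasisError("index values must be non-empty and finite")
    if np.unique(vals).size < order + 1:
        raise DegenerateBasisError(
            f"need at least {order + 1} distinct index values for an order-{order} basis"
        )
    if n_interior < 0:
        raise ValueError("n_interior must be >= 0")
    a, b = float(vals.min()), float(vals.max())
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        knots = np.quantile(vals, probs)
        knots = np.unique(knots[(knots > a) & (knots < b)])
    else:
        knots = np.empty(0)
    return SplineBasis(order=order, boundary=(a, b), interior=knots)


def eval_basis(basis: SplineBasis, u: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at ``u`` (clamped); rows sum to one."""
    uc = np.atleast_1d(basis.clamp(u))
    mat = BSpline.design_matrix(uc, basis.knot_vector, basis.order - 1)
    return np.asarray(mat.todense())


def eval_basis_deriv(basis: SplineBasis, u: np.ndarray) -> np.ndarray:
    """First derivatives of the basis functions at ``u``; rows sum to zero.

    Uses the degree-lowering recurrence
    ``B'_{j,k}(u) = k { B_{j,k-1}(u)/(t_{j+k}-t_j) - B_{j+1,k-1}(u)/(t_{j+k+1}-t_{j+1}) }``.
    At the right boundary the derivative is the left limit.
    """
    if basis.order < 2:
        raise ValueError("derivative undefined for order-1 (piecewise constant) basis")
    k = basis.order - 1  # polynomial degree
    t = basis.knot_vector
    J = basis.dimension
    a, b = basis.boundary
    uc = np.atleast_1d(basis.clamp(u))
    # step inside the right endpoint: degree-(k-1) design is left-continuous there
    eps = 1e-12 * max(abs(a), abs(b), 1.0)
    uc = np.minimum(uc, b - eps)
    # degree-(k-1) basis on the trimmed knot vector: columns are the J-1
    # non-degenerate lower-degree splines B_{1,k-1} .. B_{J-1,k-1}
    lower = np.asarray(BSpline.design_matrix(uc, t[1:-1], k - 1).todense())
    out = np.zeros((uc.size, J))
    for j in range(J):
        if 1 <= j <= J - 1:
            denom = t[j + k] - t[j]
            if denom > 0:
                out[:, j] += k * lower[:, j - 1] / denom
        if j <= J - 2:
            denom = t[j + k + 1] - t[j + 1]
            if denom > 0:
                out[:, j] -= k * lower[:, j] / denom
    return out
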