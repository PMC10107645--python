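"""Non-negative M-spline basis for baseline hazards.

The baseline hazard is modelled as h0(t) = sum_u theta_u * psi_u(t) with
theta_u >= 0, where the psi_u are M-splines: non-negative piecewise
polynomials with local support that each integrate to one over the basis
interval [a, b].  Their running integrals Psi_u (I-splines) are monotone
non-decreasing with Psi_u(a) = 0 and Psi_u(b) = 1, so the cumulative
baseline hazard H0(t) = sum_u theta_u * Psi_u(t) is non-decreasing for any
non-negative theta.

M-splines are rescaled B-splines: with knot vector T (boundary knots
repeated `order` times) and B_u the u-th B-spline of the given order,

    psi_u(t) = order / (T[u + order] - T[u]) * B_u(t),

which is the conventional unit-integral normalisation.  The roughness
penalty matrix R has entries r_uv = integral of psi_u''(t) psi_v''(t) dt;
for cubic splines the integrand is piecewise quadratic, so a two-point
Gauss-Legendre rule per inter-knot segment integrates it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline


class DegenerateSupportError(ValueError):
    """All observed times coincide, leaving no interval to support a basis."""


@dataclass(frozen=True)
class SplineBasis:
    """Cubic M-spline basis on [a, b] with its cumulative and penalty forms.

    Attributes
    ----------
    interior_knots : ndarray
        Strictly increasing knots in the open interval (a, b).
    boundary : tuple of float
        The interval [a, b]; a and b are the minimum and maximum finite
        observed survival times.
    order : int
        Spline order (cubic = 4).
    """

    interior_knots: np.ndarray
    boundary: tuple[float, float]
    order: int = 4
    _splines: list = field(default_factory=list, repr=False, compare=False)
    _cum_splines: list = field(default_factory=list, repr=False, compare=False)
    _d2_splines: list = field(default_factory=list, repr=False, compare=False)
    _R: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def m(self) -> int:
        """Number of basis functions: interior knot count + order."""
        return len(self.interior_knots) + self.order

    @property
    def knot_vector(self) -> np.ndarray:
        a, b = self.boundary
        return np.concatenate(
            [np.full(self.order, a), self.interior_knots, np.full(self.order, b)]
        )

    @property
    def R(self) -> np.ndarray:
        """m x m roughness penalty matrix, r_uv = int psi_u'' psi_v'' dt."""
        if self._R is None:
            object.__setattr__(self, "_R", penalty_matrix(self))
        return self._R

    # -- evaluation ------------------------------------------------------

    def _clamp(self, t):
        a, b = self.boundary
        return np.clip(np.asarray(t, dtype=float), a, b)

    def eval(self, t):
        """Evaluate all psi_u at times t; rows index t, columns index u.

        Times outside [a, b] are clamped to the nearest boundary.
        """
        tt = np.atleast_1d(self._clamp(t))
        out = np.empty((tt.size, self.m))
        for u, spl in enumerate(self._splines):
            out[:, u] = spl(tt)
        out[~np.isfinite(out)] = 0.0
        np.maximum(out, 0.0, out=out)
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out

    def eval_cum(self, t):
        """Evaluate all Psi_u(t) = int_a^t psi_u(s) ds (I-splines).

        Zero below a; constant at Psi_u(b) = 1 above b (the hazard is
        estimated on [a, b] only and H0 extends flat beyond b).
        """
        tt = np.atleast_1d(self._clamp(t))
        out = np.empty((tt.size, self.m))
        for u, spl in enumerate(self._cum_splines):
            out[:, u] = spl(tt)
        out[~np.isfinite(out)] = 0.0
        np.clip(out, 0.0, None, out=out)
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out

    def eval_d2(self, t):
        """Second derivatives psi_u''(t) (piecewise linear for cubics)."""
        tt = np.atleast_1d(self._clamp(t))
        out = np.empty((tt.size, self.m))
        for u, spl in enumerate(self._d2_splines):
            out[:, u] = spl(tt)
        out[~np.isfinite(out)] = 0.0
        if np.isscalar(t) or np.ndim(t) == 0:
            return out[0]
        return out

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "interior_knots": [float(k) for k in self.interior_knots],
            "boundary": [float(self.boundary[0]), float(self.boundary[1])],
            "order": int(self.order),
            "m": int(self.m),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return make_basis(
            np.asarray(d["interior_knots"], dtype=float),
            (float(d["boundary"][0]), float(d["boundary"][1])),
            int(d["order"]),
        )


def make_basis(interior_knots, boundary, order: int = 4) -> SplineBasis:
    """Construct a SplineBasis from explicit knots (low-level constructor)."""
    a, b = float(boundary[0]), float(boundary[1])
    if not b > a:
        raise DegenerateSupportError(
            f"basis interval [{a}, {b}] has zero length"
        )
    ik = np.sort(np.asarray(interior_knots, dtype=float))
    if ik.size and not (a < ik[0] and ik[-1] < b):
        raise ValueError("interior knots must lie strictly inside (a, b)")
    basis = SplineBasis(interior_knots=ik, boundary=(a, b), order=order)
    T = basis.knot_vector
    deg = order - 1
    for u in range(basis.m):
        coef = np.zeros(basis.m)
        coef[u] = 1.0
        scale = order / (T[u + order] - T[u])
        spl = BSpline(T, scale * coef, deg, extrapolate=False)
        basis._splines.append(spl)
        anti = spl.antiderivative()
        # shift so that Psi_u(a) = 0 exactly
        shift = float(anti(a))
        basis._cum_splines.append(_Shifted(anti, shift))
        if order >= 3:
            basis._d2_splines.append(spl.derivative(2))
    return basis


class _Shifted:
    """Callable wrapping a spline with a constant offset removed."""

    def __init__(self, spl, shift):
        self.spl = spl
        self.shift = shift

    def __call__(self, t):
        return self.spl(t) - self.shift


def build_basis(times, n0: int, m_override: int | None = None,
                order: int = 4) -> SplineBasis:
    """Build the default basis from observed survival times.

    Parameters
    ----------
    times : array-like
        All observed interval endpoints (event, left, right and interval
        censoring times).  Zeros and infinities are discarded: the basis
        interval [a, b] spans the minimum and maximum of the remaining
        finite positive times.
    n0 : int
        Number of non-right-censored subjects.  The basis dimension follows
        the cube-root guideline m = n0^(1/3), floored at `order` so the
        spline space is well defined; interior knots (m - order of them) are
        placed at equally spaced quantiles of the finite observed times.
    m_override : int, optional
        Explicit basis dimension, overriding the cube-root rule.
    """
    t = np.asarray(times, dtype=float)
    t = t[np.isfinite(t) & (t > 0)]
    if t.size == 0:
        raise ValueError("no finite positive observed times")
    if n0 < 1:
        raise ValueError("need at least one non-right-censored subject")
    a, b = float(t.min()), float(t.max())
    if not b > a:
        raise DegenerateSupportError("all observed times are identical")
    if m_override is not None:
        if m_override < 1:
            raise ValueError("m_override must be a positive integer")
        if m_override < order:
            raise ValueError(f"basis dimension must be at least order={order}")
        m = int(m_override)
    else:
        m = max(order, int(round(n0 ** (1.0 / 3.0))))
    n_int = m - order
    if n_int > 0:
        qs = np.linspace(0, 1, n_int + 2)[1:-1]
        ik = np.quantile(t, qs)
        # keep knots strictly interior and distinct
        ik = np.unique(ik[(ik > a) & (ik < b)])
    else:
        ik = np.empty(0)
    return make_basis(ik, (a, b), order)


def penalty_matrix(basis: SplineBasis) -> np.ndarray:
    """Exact roughness penalty R, r_uv = int_a^b psi_u''(t) psi_v''(t) dt.

    psi'' is a piecewise polynomial of degree order-3 on each inter-knot
    segment, so the integrand has degree 2(order-3) and an (order-2)-point
    Gauss-Legendre rule per segment is exact (2 points for cubics).
    """
    if basis.order < 3:
        raise ValueError("penalty requires order >= 3 for second derivatives")
    npts = max(1, basis.order - 2)
    nodes, weights = leggauss(npts)
    a, b = basis.boundary
    edges = np.unique(np.concatenate([[a], basis.interior_knots, [b]]))
    pts, wts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = 0.5 * (hi - lo)
        pts.append(0.5 * (lo + hi) + half * nodes)
        wts.append(half * weights)
    pts = np.concatenate(pts)
    wts = np.concatenate(wts)
    D2 = basis.eval_d2(pts)
    R = (D2 * wts[:, None]).T @ D2
    return 0.5 * (R + R.T)
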