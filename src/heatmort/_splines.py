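"""Natural cubic spline bases with linear tails.

The basis is the classical natural cubic spline construction: a cubic
B-spline basis on the given knots, projected onto the null space of the
second-derivative constraints at the two boundary knots.  Outside the
boundary the basis continues linearly (first-order Taylor expansion at the
boundary), which is the behaviour that makes log-linear extrapolation of a
fitted log-relative-risk curve automatic.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["NaturalSpline"]


class NaturalSpline:
    """Natural cubic spline design on fixed knots.

    Parameters
    ----------
    knots : array-like
        Interior knots, strictly inside ``boundary``.
    boundary : (float, float)
        Boundary knots.  Second derivatives vanish here and the basis is
        linear beyond them.
    intercept : bool, default False
        If True the basis spans constants (dimension ``len(knots) + 2``);
        otherwise the first column is dropped (dimension ``len(knots) + 1``),
        the convention for an exposure basis used inside a regression that
        carries its own intercept.
    """

    def __init__(self, knots, boundary, intercept: bool = False):
        knots = np.atleast_1d(np.asarray(knots, dtype=float))
        lo, hi = float(boundary[0]), float(boundary[1])
        if not lo < hi:
            raise ValueError(f"degenerate boundary knots ({lo}, {hi})")
        if knots.size and (np.any(knots <= lo) | np.any(knots >= hi)):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("interior knots must be strictly increasing")
        self.knots = knots
        self.boundary = (lo, hi)
        self.intercept = bool(intercept)

        t = np.r_[[lo] * 4, knots, [hi] * 4]
        n_b = knots.size + 4
        # without intercept, drop the first B-spline (1 = sum of all B-splines,
        # so the remaining columns plus a constant still span the full space)
        coef = np.eye(n_b) if intercept else np.eye(n_b)[:, 1:]
        self._bspl = BSpline(t, coef, 3, extrapolate=False)
        # null space of the 2nd-derivative constraints at the boundaries
        d2 = self._bspl.derivative(2)(np.array([lo, hi]))
        q, _ = np.linalg.qr(d2.T, mode="complete")
        h = q[:, 2:]
        # fix QR sign ambiguity so the basis is reproducible across platforms
        sign = np.sign(h[np.argmax(np.abs(h) > 1e-12, axis=0), np.arange(h.shape[1])])
        sign[sign == 0] = 1.0
        self._H = h * sign
        self.df = self._H.shape[1]
        # cache boundary values/slopes for the linear tails
        b = np.array([lo, hi])
        self._b_val = self._eval_inside(b)
        self._b_slope = self._bspl.derivative(1)(b) @ self._H

    def _eval_inside(self, x):
        out = self._bspl(x) @ self._H
        return np.nan_to_num(out, copy=False)

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at ``x`` (linear beyond the boundary knots)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in spline input")
        lo, hi = self.boundary
        xc = np.clip(x, lo, hi)
        out = self._eval_inside(xc)
        below, above = x < lo, x > hi
        if np.any(below):
            out[below] = self._b_val[0] + np.outer(x[below] - lo, self._b_slope[0])
        if np.any(above):
            out[above] = self._b_val[1] + np.outer(x[above] - hi, self._b_slope[1])
        return out

    def __call__(self, x) -> np.ndarray:
        return self.design(x)

    @classmethod
    def from_percentiles(cls, values, percentiles=(10.0, 75.0, 90.0), boundary=None,
                         intercept: bool = False) -> "NaturalSpline":
        """Place interior knots at percentiles of observed ``values``.

        Boundary defaults to the observed min/max.  Raises on degenerate
        (near-constant) series, where knots collapse.
        """
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise ValueError("no finite values to place knots on")
        knots = np.percentile(values, list(percentiles))
        if boundary is None:
            boundary = (values.min(), values.max())
        if np.any(np.diff(knots) <= 0) or knots[0] <= boundary[0] or knots[-1] >= boundary[1]:
            raise ValueError("degenerate temperature distribution: knots collapse")
        return cls(knots, boundary, intercept=intercept)
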