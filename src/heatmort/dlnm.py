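"""First-stage temperature–mortality estimation.

A distributed-lag non-linear model (DLNM): daily death counts are regressed
on a cross-basis — the tensor product of a natural cubic spline in
temperature (exposure dimension) and a natural cubic spline in lag
(0..21 days) — with quasi-Poisson (log link, Pearson-scaled) errors,
adjusting for long-term trend and seasonality through a natural cubic
spline of time with 8 df per year, and for day of week.

The fitted exposure–lag–response surface is then reduced to the
one-dimensional *cumulative* exposure–response curve by summing the lag
basis over lags, and centred at the minimum mortality temperature (MMT).

Default specification: exposure knots at the 10th/75th/90th percentiles of
the observed temperature distribution (boundary at the observed min/max),
lag knots log-spaced up to 21 days, which yields a 4 x 4 = 16 column
cross-basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._splines import NaturalSpline

__all__ = [
    "BasisSpec",
    "CrossBasis",
    "CumulativeCurve",
    "DistributedLagModel",
    "build_cross_basis",
    "fit_first_stage",
    "reduce_to_cumulative",
    "find_mmt",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class BasisSpec:
    """Specification of both cross-basis dimensions.

    ``lag_knots`` are placed ("log" or "linear" spacing) at values ending at
    ``lag_max``; the final knot coincides with the upper boundary, so the
    intercept-bearing lag basis has dimension ``n_lag_knots + 1``.
    """

    var_knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0)
    lag_max: int = 21
    n_lag_knots: int = 3
    lag_knot_scale: str = "log"

    def __post_init__(self):
        p = self.var_knot_percentiles
        if any(not 0 < q < 100 for q in p) or any(a >= b for a, b in zip(p, p[1:])):
            raise ValueError("knot percentiles must be strictly increasing in (0, 100)")
        if self.lag_max < 1:
            raise ValueError("lag_max must be >= 1")
        if self.lag_knot_scale not in ("log", "linear"):
            raise ValueError("lag_knot_scale must be 'log' or 'linear'")

    def lag_knot_values(self) -> np.ndarray:
        k, L = self.n_lag_knots, self.lag_max
        if self.lag_knot_scale == "log":
            return L ** (np.arange(1, k + 1) / k)
        return L * np.arange(1, k + 1) / k

    def lag_basis(self) -> NaturalSpline:
        knots = self.lag_knot_values()
        return NaturalSpline(knots[:-1], (0.0, float(self.lag_max)), intercept=True)

    def var_basis(self, temps) -> NaturalSpline:
        return NaturalSpline.from_percentiles(
            temps, percentiles=self.var_knot_percentiles, intercept=False)


@dataclass
class CrossBasis:
    """Cross-basis design for one location's temperature series.

    Column ``j * v_l + k`` at row ``t`` is the finite sum over lags
    ``sum_l Bx_j(T_{t-l}) * Bl_k(l)``.  The first ``lag_max`` rows have an
    incomplete lag window and are flagged in ``incomplete``.
    """

    matrix: np.ndarray
    spec: BasisSpec
    var_basis: NaturalSpline
    lag_basis_matrix: np.ndarray   # (lag_max+1, v_l)
    incomplete: np.ndarray         # bool, True where lag window incomplete
    temps: np.ndarray

    @property
    def v_x(self) -> int:
        return self.var_basis.df

    @property
    def v_l(self) -> int:
        return self.lag_basis_matrix.shape[1]

    @property
    def lag_sums(self) -> np.ndarray:
        """s_k = sum_l Bl_k(l) — the reduction weights."""
        return self.lag_basis_matrix.sum(axis=0)


def build_cross_basis(temps, spec: BasisSpec | None = None) -> CrossBasis:
    spec = spec or BasisSpec()
    t = np.asarray(temps, dtype=float) if not isinstance(temps, pd.Series) else temps.to_numpy()
    if len(t) <= spec.lag_max:
        raise ValueError("series must be longer than lag_max")
    vb = spec.var_basis(t)
    lb = spec.lag_basis()
    B_l = lb.design(np.arange(spec.lag_max + 1, dtype=float))
    B_x = vb.design(t)
    n, v_x = B_x.shape
    v_l = B_l.shape[1]
    cb = np.empty((n, v_x * v_l))
    for j in range(v_x):
        for k in range(v_l):
            cb[:, j * v_l + k] = np.convolve(B_x[:, j], B_l[:, k], mode="full")[:n]
    incomplete = np.zeros(n, dtype=bool)
    incomplete[: spec.lag_max] = True
    return CrossBasis(matrix=cb, spec=spec, var_basis=vb,
                      lag_basis_matrix=B_l, incomplete=incomplete, temps=t)


@dataclass
class CumulativeCurve:
    """Reduced cumulative exposure–response: log RR as a function of daily
    mean temperature on the exposure spline basis, centred at the MMT."""

    beta: np.ndarray
    vcov: np.ndarray
    knots: np.ndarray
    boundary: tuple[float, float]
    mmt: float | None = None
    temp_percentiles: dict[str, float] = field(default_factory=dict)

    def basis(self) -> NaturalSpline:
        return NaturalSpline(self.knots, self.boundary, intercept=False)

    def log_rr(self, temps, ref: float | None = None) -> np.ndarray:
        """Centred log relative risk; linear in log RR beyond the observed
        boundary (the natural spline's linear tails)."""
        ref = self.mmt if ref is None else ref
        if ref is None:
            raise ValueError("no reference temperature: set the MMT first")
        b = self.basis()
        return (b.design(temps) - b.design([ref])) @ self.beta

    def log_rr_se(self, temps, ref: float | None = None) -> np.ndarray:
        ref = self.mmt if ref is None else ref
        b = self.basis()
        X = b.design(temps) - b.design([ref])
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.vcov, X), 0.0))

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "beta": self.beta.tolist(),
            "vcov": self.vcov.tolist(),
            "knots": np.asarray(self.knots).tolist(),
            "boundary": list(self.boundary),
            "mmt": self.mmt,
            "temp_percentiles": self.temp_percentiles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CumulativeCurve":
        return cls(beta=np.asarray(d["beta"]), vcov=np.asarray(d["vcov"]),
                   knots=np.asarray(d["knots"]), boundary=tuple(d["boundary"]),
                   mmt=d.get("mmt"), temp_percentiles=d.get("temp_percentiles", {}))


def _time_spline(dates: pd.DatetimeIndex, df_per_year: float) -> np.ndarray:
    """Natural cubic spline of time with round(df_per_year * n_years) total df
    (leap days counted as day fractions), knots at equally spaced dates."""
    t = (dates - dates[0]).days.to_numpy(dtype=float)
    n_years = (t[-1] + 1) / 365.25
    df = max(int(round(df_per_year * n_years)), 2)
    knots = np.linspace(t[0], t[-1], df + 1)[1:-1]
    return NaturalSpline(knots, (t[0], t[-1]), intercept=False).design(t)


def fit_first_stage(deaths: pd.Series, cb: CrossBasis, df_per_year: float = 8.0
                    ) -> "DistributedLagModel":
    """Convenience wrapper over :class:`DistributedLagModel`."""
    model = DistributedLagModel(spec=cb.spec, df_per_year=df_per_year)
    temps = pd.Series(cb.temps, index=deaths.index)
    return model.fit(temps, deaths, cross_basis=cb)


class DistributedLagModel:
    """Quasi-Poisson DLNM estimator (scikit-learn style).

    Parameters
    ----------
    spec : BasisSpec
        Cross-basis specification.
    df_per_year : float
        Degrees of freedom per year of the seasonal/trend time spline.
    mmt_percentile_range : (float, float)
        Search range for the minimum mortality temperature, as percentiles
        of the observed temperatures.
    mmt_grid_step : float
        Grid resolution (°C) of the MMT search.

    Fitted attributes (trailing underscore): ``coef_``, ``cov_``,
    ``dispersion_``, ``curve_`` (the centred :class:`CumulativeCurve`),
    ``converged_``.
    """

    def __init__(self, spec: BasisSpec | None = None, df_per_year: float = 8.0,
                 mmt_percentile_range: tuple[float, float] = (1.0, 99.0),
                 mmt_grid_step: float = 0.1):
        self.spec = spec or BasisSpec()
        self.df_per_year = df_per_year
        self.mmt_percentile_range = mmt_percentile_range
        self.mmt_grid_step = mmt_grid_step

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "df_per_year": self.df_per_year,
                "mmt_percentile_range": self.mmt_percentile_range,
                "mmt_grid_step": self.mmt_grid_step}

    def set_params(self, **params) -> "DistributedLagModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -----------------------------------------------------------------------
    def fit(self, temps: pd.Series, deaths: pd.Series,
            cross_basis: CrossBasis | None = None) -> "DistributedLagModel":
        """Fit to one location's aligned daily temperature and death series.

        Rows with an incomplete lag window (the first ``lag_max`` days) and
        rows with missing deaths or temperature are dropped from the
        likelihood.
        """
        if not temps.index.equals(deaths.index):
            raise ValueError("temperature and death series are not aligned")
        dates = pd.DatetimeIndex(temps.index)
        n_years = len(dates) / 365.25
        if n_years < 1.0:
            raise ValueError("need at least one full year of data")
        y = deaths.to_numpy(dtype=float)
        if np.nansum(y) == 0:
            raise ValueError("all death counts are zero")

        cb = cross_basis if cross_basis is not None else build_cross_basis(temps, self.spec)
        time_sp = _time_spline(dates, self.df_per_year)
        dow = pd.get_dummies(dates.dayofweek, drop_first=True, dtype=float).to_numpy()
        X = np.column_stack([np.ones(len(y)), cb.matrix, time_sp, dow])
        keep = ~cb.incomplete & np.isfinite(y) & np.isfinite(cb.temps) & np.isfinite(X).all(axis=1)

        res = sm.GLM(y[keep], X[keep], family=sm.families.Poisson()).fit(scale="X2")
        if not np.all(np.isfinite(res.params)):
            raise ConvergenceError("IRLS produced non-finite coefficients")
        self.converged_ = bool(getattr(res, "converged", True))
        self.coef_ = res.params
        self.cov_ = np.asarray(res.cov_params())
        self.dispersion_ = float(res.scale)
        self.cross_basis_ = cb
        self.n_obs_ = int(keep.sum())
        self._cb_slice = slice(1, 1 + cb.matrix.shape[1])
        self.curve_ = reduce_to_cumulative(self, cb)
        self.curve_.mmt = find_mmt(self.curve_, self.mmt_percentile_range,
                                   grid_step=self.mmt_grid_step)
        return self

    def predict_log_rr(self, temps, ref: float | None = None) -> np.ndarray:
        """Cumulative (over lags) log relative risk at given temperatures."""
        return self.curve_.log_rr(temps, ref=ref)

    @property
    def crossbasis_coef_(self) -> np.ndarray:
        return self.coef_[self._cb_slice]

    @property
    def crossbasis_cov_(self) -> np.ndarray:
        return self.cov_[self._cb_slice, self._cb_slice]


def reduce_to_cumulative(fit: DistributedLagModel, cb: CrossBasis) -> CumulativeCurve:
    """Sum the lag dimension out of the fitted surface.

    With cross-basis columns ordered exposure-major, the reduced coefficient
    vector is ``beta_red = (I_vx (x) s)^T beta_cb`` with ``s`` the lag-basis
    column sums; the covariance maps through the same linear operator.
    """
    s = cb.lag_sums
    M = np.kron(np.eye(cb.v_x), s)          # (v_x, v_x * v_l)
    beta_red = M @ fit.crossbasis_coef_
    v_red = M @ fit.crossbasis_cov_ @ M.T
    v_red = (v_red + v_red.T) / 2.0
    t = cb.temps[np.isfinite(cb.temps)]
    pct = {"p1": float(np.percentile(t, 1)), "p50": float(np.percentile(t, 50)),
           "p99": float(np.percentile(t, 99))}
    return CumulativeCurve(beta=beta_red, vcov=v_red,
                           knots=cb.var_basis.knots,
                           boundary=cb.var_basis.boundary,
                           temp_percentiles=pct)


def find_mmt(curve: CumulativeCurve, percentile_range: tuple[float, float] = (1.0, 99.0),
             grid_step: float = 0.1, temps=None) -> float:
    """Minimum mortality temperature: grid minimiser of the un-centred curve.

    The grid spans the given percentiles of the observed temperatures
    (stored on the curve, or recomputed from ``temps``); ties break toward
    the observed median.
    """
    if temps is not None:
        t = np.asarray(temps, dtype=float)
        lo, hi = np.percentile(t, list(percentile_range))
        med = float(np.median(t))
    else:
        pct = curve.temp_percentiles
        if not pct:
            raise ValueError("curve carries no temperature percentiles; pass temps")
        lo, hi, med = pct["p1"], pct["p99"], pct["p50"]
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = curve.basis().design(grid) @ curve.beta
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite curve values in MMT search")
    winners = np.flatnonzero(vals <= vals.min() + 1e-12)
    return float(grid[winners[np.argmin(np.abs(grid[winners] - med))]])


def save_curves(curves: dict[str, CumulativeCurve], path: str | Path) -> None:
    doc = {"schema_version": 1,
           "curves": {k: c.to_dict() for k, c in curves.items()}}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_curves(path: str | Path) -> dict[str, CumulativeCurve]:
    doc = json.loads(Path(path).read_text())
    return {k: CumulativeCurve.from_dict(d) for k, d in doc["curves"].items()}
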