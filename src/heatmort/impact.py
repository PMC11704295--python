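"""Heat-attributable mortality projection at global warming levels.

For each day of a bias-corrected 20-year model window with temperature
above the minimum mortality temperature, the attributable fraction is
``AF = (RR - 1) / RR`` with ``RR = exp(logRR(T))`` from the cumulative
exposure–response curve (log-linearly extrapolated beyond the observed
temperature range by the natural spline's linear tails).  Attributable
deaths are ``AF x baseline daily deaths``, annualised over the 20-year
window; the heat-mortality fraction ``h`` divides by total annual deaths
(baseline x 365.25) and so is invariant to the baseline.

Uncertainty: Monte-Carlo empirical confidence intervals.  Coefficient
vectors are drawn from the BLUP's multivariate normal; for each draw the
MMT is re-found and ``h`` recomputed for every climate model's window; the
draws x models values are pooled into one empirical distribution whose
2.5/50/97.5 percentiles give the best/average/worst cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._splines import NaturalSpline
from .dlnm import CumulativeCurve

__all__ = [
    "ImpactResult",
    "extrapolate_curve",
    "attributable_deaths",
    "monte_carlo_ci",
    "summarize_cases",
]

DAYS_PER_YEAR = 365.25


@dataclass
class ImpactResult:
    """Projected heat burden for one location at one warming level."""

    location: str
    level: float
    per_model_an: dict[str, float]      # annual attributable deaths, point estimate
    per_model_h: dict[str, float]       # annual heat fraction, point estimate
    ci_lower: float
    ci_median: float
    ci_upper: float
    n_sim: int
    seed: int | None = None
    draws_h: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.ci_lower <= self.ci_median <= self.ci_upper:
            raise ValueError("empirical CI bounds out of order")


def extrapolate_curve(curve: CumulativeCurve, temps) -> np.ndarray:
    """Cumulative log RR at any finite temperature, centred at the MMT.

    Inside the observed boundary this is the natural-spline evaluation;
    beyond it the curve continues linearly in log RR with the boundary
    slope (continuous, with continuous first derivative).
    """
    return curve.log_rr(temps)


def attributable_deaths(temps_window: pd.Series | np.ndarray, curve: CumulativeCurve,
                        baseline_daily_deaths: float,
                        window_years: float = 20.0) -> tuple[float, float]:
    """(annual attributable deaths AN, annual heat fraction h) over a window."""
    if baseline_daily_deaths <= 0:
        raise ValueError("baseline_daily_deaths must be positive")
    t = np.asarray(temps_window, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature window")
    if curve.mmt is None:
        raise ValueError("curve has no MMT set")
    log_rr = curve.log_rr(t)
    rr = np.exp(log_rr)
    # attribution counts heat excess only: clamp at 0 where RR dips below 1
    af = np.where(t > curve.mmt, np.maximum((rr - 1.0) / rr, 0.0), 0.0)
    an = float(af.sum() * baseline_daily_deaths / window_years)
    h = an / (baseline_daily_deaths * DAYS_PER_YEAR)
    return an, float(h)


def _h_for_draws(basis: NaturalSpline, betas: np.ndarray, temps: np.ndarray,
                 grid: np.ndarray, grid_design: np.ndarray,
                 fixed_mmt: float | None = None) -> np.ndarray:
    """Heat fraction per coefficient draw, re-finding the MMT per draw."""
    if fixed_mmt is None:
        gvals = grid_design @ betas.T                      # (n_grid, n_draw)
        mmt_idx = np.argmin(gvals, axis=0)
        mmts = grid[mmt_idx]
        ref = np.take_along_axis(gvals, mmt_idx[None, :], axis=0)[0]
    else:
        mmts = np.full(betas.shape[0], fixed_mmt)
        ref = basis.design([fixed_mmt]) @ betas.T
        ref = np.asarray(ref).ravel()
    logrr = basis.design(temps) @ betas.T - ref[None, :]   # (n_days, n_draw)
    rr = np.exp(logrr)
    af = np.where(temps[:, None] > mmts[None, :],
                  np.maximum((rr - 1.0) / rr, 0.0), 0.0)
    return af.mean(axis=0)                                 # == h by baseline cancelling


def monte_carlo_ci(curve: CumulativeCurve, window_temps: dict[str, np.ndarray],
                   location: str, level: float, n_sim: int = 1000,
                   seed: int | np.random.SeedSequence | None = None,
                   baseline_daily_deaths: float = 1.0,
                   refind_mmt: bool = True) -> ImpactResult | None:
    """Empirical confidence intervals for the annual heat fraction.

    ``window_temps`` maps model_id to that model's bias-corrected daily
    temperatures over its 20-year window at this level.  Coefficient draws
    combine with every model window; all draw x model values are pooled.
    Returns None (with the caller expected to warn) when no model reaches
    the level.
    """
    if len(window_temps) == 0:
        return None
    rng = np.random.default_rng(seed)
    v = np.asarray(curve.vcov)
    v = (v + v.T) / 2.0
    w, U = np.linalg.eigh(v)
    L = U * np.sqrt(np.maximum(w, 0.0))
    betas = curve.beta[None, :] + rng.standard_normal((n_sim, len(curve.beta))) @ L.T

    basis = curve.basis()
    pct = curve.temp_percentiles
    grid = np.arange(pct["p1"], pct["p99"] + 0.05, 0.1)
    grid_design = basis.design(grid)
    per_model_an, per_model_h, pooled = {}, {}, []
    years = 20.0
    for model_id, temps in window_temps.items():
        temps = np.asarray(temps, dtype=float)
        an, h = attributable_deaths(temps, curve, baseline_daily_deaths, window_years=years)
        per_model_an[model_id], per_model_h[model_id] = an, h
        pooled.append(_h_for_draws(basis, betas, temps, grid, grid_design,
                                   fixed_mmt=None if refind_mmt else curve.mmt))
    draws = np.concatenate(pooled)
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return ImpactResult(location=location, level=level,
                        per_model_an=per_model_an, per_model_h=per_model_h,
                        ci_lower=float(lo), ci_median=float(med), ci_upper=float(hi),
                        n_sim=n_sim,
                        seed=seed if isinstance(seed, (int, np.integer)) else None,
                        draws_h=draws)


def summarize_cases(result: ImpactResult) -> dict[str, float]:
    """best = lower bound (fewest heat deaths), average = median,
    worst = upper bound of the pooled Monte-Carlo distribution."""
    return {"best": result.ci_lower, "average": result.ci_median,
            "worst": result.ci_upper}


def impact_table(results: list[ImpactResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for m in r.per_model_h:
            rows.append({"location": r.location, "level": r.level, "model_id": m,
                         "AN_per_year": r.per_model_an[m],
                         "heat_fraction": r.per_model_h[m],
                         "ci_lower": r.ci_lower, "ci_median": r.ci_median,
                         "ci_upper": r.ci_upper, "n_sim": r.n_sim, "seed": r.seed})
        rows.append({"location": r.location, "level": r.level, "model_id": "ensemble",
                     "AN_per_year": np.median(list(r.per_model_an.values())),
                     "heat_fraction": np.median(list(r.per_model_h.values())),
                     "ci_lower": r.ci_lower, "ci_median": r.ci_median,
                     "ci_upper": r.ci_upper, "n_sim": r.n_sim, "seed": r.seed})
    return pd.DataFrame(rows)
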