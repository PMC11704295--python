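"""Self-contained validation experiments for the whole pipeline.

Each function generates its own synthetic inputs (known ground truth),
runs the relevant stage(s), and returns the measured quantity — oracle
agreement, recovery error, coverage, closure — so the package's behaviour
can be audited end to end from a single seed.  Problem sizes are chosen so
the full battery runs in minutes on one CPU; the methods note records them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._splines import NaturalSpline
from .simulate import (SimConfig, generate_temperature_series,
                       generate_mortality_series, generate_model_series,
                       generate_metadata, location_curve, true_heat_fraction)
from .dlnm import BasisSpec, build_cross_basis, DistributedLagModel
from .meta import build_meta_predictors, fit_meta_regression, compute_blups
from .climate import compute_gwl_windows, QuantileMapper
from .impact import attributable_deaths, monte_carlo_ci
from .comparison import years_to_equal, covid_fraction

__all__ = [
    "worked_example_years",
    "crossbasis_max_deviation",
    "reduction_max_deviation",
    "recovery_study",
    "quantile_map_checks",
    "gwl_window_checks",
    "end_to_end_study",
    "mc_degenerate_width",
]

LEVELS = (1.0, 1.5, 2.0, 3.0)


def _sub(seed: int, k: int) -> int:
    """Independent 31-bit sub-seed from a master seed."""
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# 1. the worked example of the headline metric
def worked_example_years() -> float:
    """20% COVID mortality for one year vs 1% heat mortality per year."""
    c = covid_fraction(2000, 1500, 10.0, 1_000_000)   # 20% of 10,000 total deaths
    return years_to_equal(c, 0.01)


# ---------------------------------------------------------------------------
# 2. cross-basis vs brute-force double sum
def _brute_force_crossbasis(temps: np.ndarray, spec: BasisSpec) -> np.ndarray:
    vb = spec.var_basis(temps)
    lb = spec.lag_basis()
    B_l = lb.design(np.arange(spec.lag_max + 1, dtype=float))
    n, vx, vl = len(temps), vb.df, B_l.shape[1]
    out = np.zeros((n, vx * vl))
    for row in range(spec.lag_max, n):
        for j in range(vx):
            for k in range(vl):
                acc = 0.0
                for lag in range(spec.lag_max + 1):
                    acc += vb.design([temps[row - lag]])[0, j] * B_l[lag, k]
                out[row, j * vl + k] = acc
    return out


def crossbasis_max_deviation(seed: int, n_instances: int = 3) -> float:
    """Max |implementation - oracle| over random instances of <= 100 days."""
    rng = np.random.default_rng(_sub(seed, 21))
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(60, 101))
        temps = rng.normal(12.0, 6.0, n) + 6 * np.sin(np.arange(n) / 30.0)
        spec = BasisSpec()
        cb = build_cross_basis(temps, spec)
        oracle = _brute_force_crossbasis(temps, spec)
        rows = ~cb.incomplete
        worst = max(worst, float(np.abs(cb.matrix[rows] - oracle[rows]).max()))
    return worst


# ---------------------------------------------------------------------------
# 3. reduction consistency: cumulative curve == summed lag-specific surface
def reduction_max_deviation(seed: int) -> float:
    cfg = SimConfig(n_locations=1, n_years=3, heterogeneity_sd=0.0,
                    seed=_sub(seed, 31))
    temps = generate_temperature_series(cfg, 0)
    deaths = generate_mortality_series(temps, cfg, 0)
    model = DistributedLagModel().fit(temps, deaths)
    cb = model.cross_basis_
    grid = np.linspace(temps.min(), temps.max(), 50)
    ref = float(np.median(temps))
    bx = cb.var_basis.design(grid) - cb.var_basis.design([ref])
    beta_full = model.crossbasis_coef_.reshape(cb.v_x, cb.v_l)
    summed = np.zeros(len(grid))
    for lag in range(cb.spec.lag_max + 1):
        summed += bx @ (beta_full @ cb.lag_basis_matrix[lag])
    reduced = model.curve_.log_rr(grid, ref=ref)
    return float(np.abs(reduced - summed).max())


# ---------------------------------------------------------------------------
# 4. parameter recovery: BLUP coverage of the true curve + MMT error
def recovery_study(seed: int, n_reps_coverage: int = 5, n_reps_mmt: int = 100,
                   n_locations: int = 10, n_years: int = 10) -> dict:
    """Pointwise 95% CI coverage of the true cumulative curve by BLUP curves
    (pooled over replicate studies, 5th-95th pct grid) and the median
    absolute MMT recovery error over single-location replicates."""
    hits = total = 0
    for rep in range(n_reps_coverage):
        cfg = SimConfig(n_locations=n_locations, n_years=n_years,
                        seed=_sub(seed, 4000 + rep))
        curves, temps_all, rows = {}, {}, []
        for i in range(n_locations):
            loc = f"loc_{i:03d}"
            temps = generate_temperature_series(cfg, i)
            deaths = generate_mortality_series(temps, cfg, i)
            curves[loc] = DistributedLagModel().fit(temps, deaths).curve_
            temps_all[loc] = temps
            rows.append(pd.DataFrame({"location_id": loc, "tmean": temps.to_numpy()}))
        X = build_meta_predictors(generate_metadata(cfg), pd.concat(rows))
        X = X[["intercept", "log_gdp_pc", "tmean_avg"]]
        model = fit_meta_regression(curves, X)
        blups = compute_blups(model, curves, X)
        # small-sample meta-analytic intervals: t quantile at the residual df
        from scipy import stats as _st
        crit = float(_st.t.ppf(0.975, model.df_resid_))
        for i in range(n_locations):
            loc = f"loc_{i:03d}"
            truth = location_curve(cfg, i)
            t = temps_all[loc].to_numpy()
            grid = np.linspace(np.percentile(t, 5), np.percentile(t, 95), 40)
            b = blups[loc]
            err = b.log_rr(grid, ref=truth.mmt) - truth.log_rr(grid)
            half = crit * b.log_rr_se(grid, ref=truth.mmt)
            hits += int(np.sum(np.abs(err) <= half))
            total += len(grid)

    mmt_errs = []
    for rep in range(n_reps_mmt):
        cfg = SimConfig(n_locations=1, n_years=n_years, heterogeneity_sd=0.0,
                        seed=_sub(seed, 5000 + rep))
        temps = generate_temperature_series(cfg, 0)
        deaths = generate_mortality_series(temps, cfg, 0)
        fit = DistributedLagModel().fit(temps, deaths)
        mmt_errs.append(abs(fit.curve_.mmt - cfg.true_curve.mmt))
    return {"coverage": hits / total,
            "mmt_median_abs_error": float(np.median(mmt_errs)),
            "n_coverage_points": total, "n_mmt_reps": n_reps_mmt}


# ---------------------------------------------------------------------------
# 5. quantile mapping: calibration closure and synthetic-bias removal
def quantile_map_checks(seed: int) -> dict:
    rng = np.random.default_rng(_sub(seed, 61))
    idx = pd.date_range("2000-01-01", periods=5 * 365, freq="D")
    station = pd.Series(rng.normal(12, 6, len(idx)), index=idx)
    model = pd.Series(1.5 * rng.normal(12, 6, len(idx)) - 4.0, index=idx)
    qm = QuantileMapper(monthly=False).fit(model, station)
    closure = float(np.abs(qm._map_values(qm.quantiles_model_[0], 0)
                           - qm.quantiles_station_[0]).max())

    # low-noise configuration: the check is about bias removal, so the AR(1)
    # mean wander (~0.08 °C at sd 1) must not swamp the 0.1 °C tolerance
    cfg = SimConfig(model_bias_mean=2.0, model_bias_sd=0.0, warming_rate=0.0,
                    warming_rate_jitter=0.0, temp_noise_sd=0.4, n_years=10,
                    n_model_years=40, seed=_sub(seed, 62))
    st = generate_temperature_series(cfg, 0)
    md, _ = generate_model_series(cfg, 0, 0)   # station-like + 2 °C bias
    mapper = QuantileMapper().fit(md.loc[st.index], st)
    corrected = mapper.transform(md)
    proj = corrected[corrected.index.year >= 2020]
    bias_residual = float(abs(proj.mean() - cfg.seasonal_temp_mean))
    return {"closure_max_abs": closure, "bias_residual_degc": bias_residual}


# ---------------------------------------------------------------------------
# 6. warming-level windows: closed form + exhaustive scan
def gwl_window_checks(seed: int, n_series: int = 25) -> dict:
    years = np.arange(0, 100)
    linear = pd.Series(0.03 * years, index=pd.Index(years, name="year"))
    w = compute_gwl_windows(linear, levels=[1.5], model_id="lin")[0]
    closed_form_err = abs(w.crossing_year - 50) + abs(w.start_year - 41)

    rng = np.random.default_rng(_sub(seed, 71))
    mismatches = 0
    import warnings as _w
    for _ in range(n_series):
        vals = np.cumsum(rng.uniform(-0.02, 0.08, 120)) + rng.normal(0, 0.1, 120)
        anom = pd.Series(vals, index=pd.Index(np.arange(1990, 2110), name="year"))
        running = np.convolve(vals, np.ones(20) / 20, mode="valid")
        for level in (0.5, 1.0, 1.5, 2.0, 3.0):
            hit = np.flatnonzero(running >= level)
            expected = int(anom.index[hit[0]]) if hit.size else None
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                got = compute_gwl_windows(anom, levels=[level])
            start = got[0].start_year if got else None
            mismatches += int(start != expected)
    return {"closed_form_abs_err_years": int(closed_form_err),
            "scan_mismatches": int(mismatches)}


# ---------------------------------------------------------------------------
# 7. end-to-end heat-fraction recovery and years-to-equal ordering
def _one_end_to_end(seed: int, n_locations: int = 3, n_models: int = 3,
                    n_sim: int | None = None) -> dict:
    """One fully synthetic study with homogeneous true curves; returns
    per-level pooled estimates, integrated truths, and (optionally)
    Monte-Carlo cases per location/level."""
    cfg = SimConfig(n_locations=n_locations, n_years=10, n_models=n_models,
                    heterogeneity_sd=0.0, seed=seed)
    cal0, cal1 = cfg.start_year, cfg.start_year + cfg.n_years - 1
    curves, temps_all, rows = {}, {}, []
    for i in range(n_locations):
        loc = f"loc_{i:03d}"
        temps = generate_temperature_series(cfg, i)
        deaths = generate_mortality_series(temps, cfg, i)
        curves[loc] = DistributedLagModel().fit(temps, deaths).curve_
        temps_all[loc] = temps
        rows.append(pd.DataFrame({"location_id": loc, "tmean": temps.to_numpy()}))
    X = build_meta_predictors(generate_metadata(cfg), pd.concat(rows)).iloc[:, :1]
    blups = compute_blups(fit_meta_regression(curves, X), curves, X)

    wins, anoms, corrected = {}, {}, {}
    for m in range(n_models):
        _, anom = generate_model_series(cfg, 0, m)
        anoms[m] = anom
        wins[m] = {w.level: w for w in
                   compute_gwl_windows(anom, LEVELS, model_id=str(m))}
    for i in range(n_locations):
        loc = f"loc_{i:03d}"
        for m in range(n_models):
            daily, _ = generate_model_series(cfg, i, m)
            qm = QuantileMapper().fit(daily.loc[temps_all[loc].index], temps_all[loc])
            corrected[(loc, m)] = qm.transform(daily)

    out = {"h_est": {}, "h_true": {}, "cases": []}
    for level in LEVELS:
        est, truth = [], []
        for i in range(n_locations):
            loc = f"loc_{i:03d}"
            tc = location_curve(cfg, i)
            window_temps = {}
            for m in range(n_models):
                w = wins[m].get(level)
                if w is None:
                    continue
                anom = anoms[m]
                delta = (anom.loc[w.start_year:w.end_year].mean()
                         - anom.loc[cal0:cal1].mean())
                truth.append(true_heat_fraction(tc, temps_all[loc].to_numpy() + delta))
                s = corrected[(loc, m)]
                mask = (s.index.year >= w.start_year) & (s.index.year <= w.end_year)
                window_temps[str(m)] = s.to_numpy()[mask]
                est.append(attributable_deaths(window_temps[str(m)],
                                               blups[loc], 1.0)[1])
            if n_sim and window_temps:
                res = monte_carlo_ci(blups[loc], window_temps, loc, level,
                                     n_sim=n_sim,
                                     seed=np.random.SeedSequence([seed, 9, i,
                                                                  int(level * 10)]))
                out["cases"].append({"location": loc, "level": level,
                                     "best": res.ci_lower, "average": res.ci_median,
                                     "worst": res.ci_upper})
        out["h_est"][level] = est
        out["h_true"][level] = truth
    return out


def end_to_end_study(seed: int, n_reps: int = 40, n_sim: int = 200) -> dict:
    """Median relative error of the pooled heat fraction per warming level
    over replicate studies, plus the years-to-equal case-ordering check on a
    Monte-Carlo run of the first replicate."""
    rel_errs: dict[float, list[float]] = {l: [] for l in LEVELS}
    ordering_violations = 0
    for rep in range(n_reps):
        res = _one_end_to_end(_sub(seed, 8000 + rep),
                              n_sim=n_sim if rep == 0 else None)
        for level in LEVELS:
            he = np.median(res["h_est"][level])
            ht = np.median(res["h_true"][level])
            rel_errs[level].append((he - ht) / ht)
        if rep == 0:
            c = 0.2
            for case in res["cases"]:
                y = {k: years_to_equal(c, case[k]) if case[k] > 0 else np.inf
                     for k in ("best", "average", "worst")}
                if not y["worst"] <= y["average"] <= y["best"]:
                    ordering_violations += 1
    return {"h_rel_err_by_level": {l: float(np.median(v)) for l, v in rel_errs.items()},
            "ordering_violations": int(ordering_violations),
            "n_reps": n_reps, "n_sim": n_sim}


# ---------------------------------------------------------------------------
# 8. Monte-Carlo degeneracy
def mc_degenerate_width(seed: int) -> float:
    """Zero coefficient covariance + one model: the eCI must be a point."""
    knots = np.array([8.0, 15.0, 20.0])
    basis = NaturalSpline(knots, (0.0, 30.0))
    x = np.linspace(0, 30, 400)
    A = np.column_stack([basis.design(x), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, 0.01 * (x - 18.0) ** 2, rcond=None)
    from .dlnm import CumulativeCurve, find_mmt
    curve = CumulativeCurve(beta=coef[:-1], vcov=np.zeros((4, 4)), knots=knots,
                            boundary=(0.0, 30.0),
                            temp_percentiles={"p1": 0.5, "p50": 15.0, "p99": 29.5})
    curve.mmt = find_mmt(curve)
    rng = np.random.default_rng(_sub(seed, 91))
    window = rng.uniform(5, 29, 7305)
    res = monte_carlo_ci(curve, {"m0": window}, "loc", 1.0, n_sim=200,
                         seed=_sub(seed, 92))
    return float(res.ci_upper - res.ci_lower)
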