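"""Warming-level windows, quantile-mapping bias correction, grid extraction."""

import numpy as np
import pandas as pd
import pytest

from heatmort.climate import (GwlWindow, QuantileMapper, compute_gwl_windows,
                              extract_nearest_gridcell)
from heatmort.simulate import SimConfig, generate_model_series, generate_temperature_series


def series(vals, start=2000):
    return pd.Series(vals, index=pd.Index(np.arange(start, start + len(vals)), name="year"))


def brute_force_windows(anomaly, level):
    """Exhaustive scan over all 20-year means (the oracle)."""
    years = anomaly.index.to_numpy()
    vals = anomaly.to_numpy()
    for i in range(len(vals) - 19):
        if vals[i:i + 20].mean() >= level:
            return int(years[i])
    return None


class TestGwlWindows:
    def test_linear_anomaly_closed_form(self):
        anom = series(0.03 * np.arange(100), start=0)
        w = compute_gwl_windows(anom, levels=[1.5], model_id="m")[0]
        assert (w.start_year, w.end_year, w.crossing_year) == (41, 60, 50)

    def test_flat_series_yields_no_windows(self):
        anom = series(np.full(60, 0.5))
        with pytest.warns(UserWarning):
            assert compute_gwl_windows(anom, levels=[1.0, 2.0]) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_scan_on_arbitrary_series(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.cumsum(rng.uniform(-0.02, 0.08, 120)) + rng.normal(0, 0.1, 120)
        anom = series(vals)
        for level in (0.5, 1.0, 1.5, 2.0):
            expected = brute_force_windows(anom, level)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = compute_gwl_windows(anom, levels=[level])
            if expected is None:
                assert got == []
            else:
                assert got[0].start_year == expected
                assert got[0].crossing_year == expected + 9

    def test_window_starts_nondecreasing_in_level(self):
        cfg = SimConfig(n_model_years=90)
        _, anom = generate_model_series(cfg, 0, 0)
        wins = compute_gwl_windows(anom, levels=[1.0, 1.5, 2.0, 3.0])
        starts = [w.start_year for w in wins]
        assert starts == sorted(starts)
        assert all(w.end_year - w.start_year + 1 == 20 for w in wins)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            compute_gwl_windows(series(np.ones(10)), levels=[1.0])

    def test_window_invariant_enforced(self):
        with pytest.raises(ValueError):
            GwlWindow("m", 1.0, 2000, 2030, 2009)


def daily(vals, start="2000-01-01"):
    return pd.Series(vals, index=pd.date_range(start, periods=len(vals), freq="D"))


class TestQuantileMapper:
    def test_identity_when_model_equals_station(self, rng):
        x = daily(rng.normal(10, 5, 3 * 365))
        qm = QuantileMapper(monthly=False).fit(x, x)
        out = qm.transform(x)
        assert np.allclose(out, x, atol=1e-10)

    def test_constant_shift_fully_corrected(self, rng):
        station = daily(rng.normal(10, 5, 3 * 365))
        model = station + 2.0
        for monthly in (False, True):
            qm = QuantileMapper(monthly=monthly).fit(model, station)
            for q in qm.quantiles_model_:
                assert np.allclose(qm.quantiles_model_[q] - qm.quantiles_station_[q],
                                   2.0, atol=1e-10)
            assert np.allclose(qm.transform(model), station, atol=1e-10)

    def test_calibration_closure_at_fitted_quantiles(self, rng):
        station = daily(rng.normal(12, 6, 5 * 365))
        model = daily(rng.normal(14, 8, 5 * 365))
        qm = QuantileMapper(monthly=False).fit(model, station)
        corrected_q = qm._map_values(qm.quantiles_model_[0], 0)
        assert np.abs(corrected_q - qm.quantiles_station_[0]).max() < 1e-6

    def test_projection_period_bias_removed(self):
        """+2 °C synthetic bias: corrected projection mean matches the
        station generator's mean plus the warming trend within 0.1 °C."""
        cfg = SimConfig(model_bias_mean=2.0, model_bias_sd=0.0, warming_rate=0.0,
                        warming_rate_jitter=0.0, temp_noise_sd=0.4,
                        n_years=10, n_model_years=40, seed=77)
        station = generate_temperature_series(cfg, 0)
        model, _ = generate_model_series(cfg, 0, 0)   # station-like + 2 °C, no trend
        # add a warming trend that starts after the calibration decade
        years_after = np.maximum(model.index.year.to_numpy() - 2009, 0).astype(float)
        model = model + 0.03 * years_after
        qm = QuantileMapper().fit(model.loc[station.index], station)
        corrected = qm.transform(model)
        proj = corrected[corrected.index.year >= 2020]
        expected_mean = (cfg.seasonal_temp_mean
                         + np.mean(0.03 * np.maximum(proj.index.year - 2009, 0)))
        assert abs(proj.mean() - expected_mean) < 0.1

    def test_monotonicity_and_rank_preservation(self, rng):
        station = daily(rng.normal(10, 4, 2 * 365))
        model = daily(rng.normal(11, 7, 2 * 365))
        qm = QuantileMapper(monthly=False).fit(model, station)
        probe = daily(rng.uniform(-20, 40, 500))
        out = qm.transform(probe)
        order = np.argsort(probe.to_numpy(), kind="stable")
        assert (np.diff(out.to_numpy()[order]) >= -1e-12).all()

    def test_empty_overlap_rejected(self, rng):
        a = daily(rng.normal(size=400), start="2000-01-01")
        b = daily(rng.normal(size=400), start="2010-01-01")
        with pytest.raises(ValueError):
            QuantileMapper().fit(a, b)

    def test_serialization_roundtrip(self, rng, tmp_path):
        station = daily(rng.normal(10, 4, 400))
        model = daily(rng.normal(12, 5, 400))
        qm = QuantileMapper().fit(model, station)
        qm.save(tmp_path / "qm.json")
        back = QuantileMapper.load(tmp_path / "qm.json")
        probe = daily(rng.uniform(-5, 30, 100))
        assert np.allclose(qm.transform(probe), back.transform(probe))


class TestNearestGridcell:
    def _grid(self, points, n_days=3):
        rows = []
        for lon, lat in points:
            for d in range(n_days):
                rows.append({"lon": lon, "lat": lat,
                             "date": f"2000-01-{d + 1:02d}",
                             "tmean": 10.0 * lat + lon + d})
        return pd.DataFrame(rows)

    def test_coincident_point_returned(self):
        grid = self._grid([(0, 0), (10, 10), (20, 20)])
        out = extract_nearest_gridcell(grid, 10.0, 10.0)
        assert np.allclose(out.to_numpy(), [110.0, 111.0, 112.0])

    def test_equidistant_tie_breaks_lexicographically(self):
        grid = self._grid([(0, 10), (0, -10)])
        out = extract_nearest_gridcell(grid, 0.0, 0.0)
        # (lat=-10, lon=0) wins lexicographic (lat, lon) order
        assert out.iloc[0] == pytest.approx(-100.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        pts = [(float(lo), float(la)) for lo, la in
               zip(rng.uniform(-180, 180, 15), rng.uniform(-80, 80, 15))]
        grid = self._grid(pts, n_days=1)
        lon0, lat0 = float(rng.uniform(-180, 180)), float(rng.uniform(-80, 80))

        def gc(lon1, lat1, lon2, lat2):
            from math import radians, sin, cos, asin, sqrt
            p1, p2 = radians(lat1), radians(lat2)
            dl = radians(lon2 - lon1)
            a = sin((p2 - p1) / 2) ** 2 + cos(p1) * cos(p2) * sin(dl / 2) ** 2
            return 2 * asin(sqrt(a))

        best = min(pts, key=lambda p: gc(p[0], p[1], lon0, lat0))
        out = extract_nearest_gridcell(grid, lon0, lat0)
        assert out.iloc[0] == pytest.approx(10.0 * best[1] + best[0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            extract_nearest_gridcell(pd.DataFrame(columns=["lon", "lat", "date", "tmean"]),
                                     0, 0)
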