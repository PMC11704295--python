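import numpy as np
import pandas as pd
import pytest

from heatmort.simulate import (SimConfig, TrueCurve, generate_temperature_series,
                               generate_mortality_series, generate_model_series,
                               generate_covid_table, generate_metadata,
                               location_curve, lag_weights, true_heat_fraction,
                               model_bias, model_warming_rate)


class TestTemperature:
    def test_degenerate_config_gives_constant_series(self):
        cfg = SimConfig(seasonal_temp_amplitude=0.0, temp_noise_sd=0.0,
                        seasonal_temp_mean=15.0, n_years=1, start_year=2001)
        t = generate_temperature_series(cfg, 0)
        assert np.allclose(t, 15.0)
        assert len(t) == 365

    def test_calendar_includes_leap_days(self):
        cfg = SimConfig(n_years=4, start_year=2000)
        t = generate_temperature_series(cfg, 0)
        assert len(t) == 4 * 365 + 1
        assert pd.Timestamp("2000-02-29") in t.index

    def test_same_seed_reproduces_bit_identical_series(self):
        cfg = SimConfig(seed=99)
        a = generate_temperature_series(cfg, 3)
        b = generate_temperature_series(cfg, 3)
        assert (a == b).all()
        c = generate_temperature_series(SimConfig(seed=100), 3)
        assert not (a == c).all()

    def test_ar1_autocorrelation_matches_coefficient(self):
        cfg = SimConfig(n_years=12, seasonal_temp_amplitude=0.0,
                        temp_ar1=0.7, temp_noise_sd=2.0, seed=11)
        x = generate_temperature_series(cfg, 0).to_numpy()
        x = x - x.mean()
        acf1 = (x[1:] @ x[:-1]) / (x @ x)
        assert abs(acf1 - 0.7) < 0.1

    @pytest.mark.parametrize("bad", [dict(temp_ar1=1.0), dict(temp_ar1=-0.1),
                                     dict(overdispersion=0.5), dict(temp_noise_sd=-1),
                                     dict(baseline_daily_deaths=-3)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestMortality:
    def test_null_curve_mean_matches_baseline(self):
        cfg = SimConfig(n_years=10, baseline_daily_deaths=50.0, overdispersion=1.0,
                        mortality_seasonal_amplitude=0.0, heterogeneity_sd=0.0,
                        true_curve=TrueCurve(curv_cold=0.0, curv_heat=0.0), seed=21)
        temps = generate_temperature_series(cfg, 0)
        deaths = generate_mortality_series(temps, cfg, 0)
        se = np.sqrt(50.0 / len(deaths))
        assert abs(deaths.mean() - 50.0) < 3 * se

    @pytest.mark.parametrize("phi", [1.0, 2.5])
    def test_variance_to_mean_ratio_matches_overdispersion(self, phi):
        # constant mean: variance/mean over many draws estimates phi
        cfg = SimConfig(n_years=1, baseline_daily_deaths=20.0, overdispersion=phi,
                        mortality_seasonal_amplitude=0.0, heterogeneity_sd=0.0,
                        seasonal_temp_amplitude=0.0, temp_noise_sd=0.0,
                        seasonal_temp_mean=19.0,  # at the true MMT: f == 0
                        seed=31)
        temps = pd.Series(np.full(60_000, 19.0),
                          index=pd.date_range("2000-01-01", periods=60_000, freq="D"))
        deaths = generate_mortality_series(temps, cfg, 0).to_numpy()
        ratio = deaths.var() / deaths.mean()
        assert ratio == pytest.approx(phi, rel=0.05)

    def test_counts_are_nonnegative_integers(self):
        cfg = SimConfig(n_years=2, seed=41)
        temps = generate_temperature_series(cfg, 0)
        d = generate_mortality_series(temps, cfg, 0)
        assert (d >= 0).all()
        assert np.issubdtype(d.dtype, np.integer)

    def test_zero_heterogeneity_shares_one_true_curve(self):
        cfg = SimConfig(heterogeneity_sd=0.0)
        assert location_curve(cfg, 0) == location_curve(cfg, 7) == cfg.true_curve
        cfg2 = SimConfig(heterogeneity_sd=1.5)
        assert location_curve(cfg2, 0) != location_curve(cfg2, 7)

    def test_lag_weights_sum_to_one(self):
        w = lag_weights(0.6)
        assert len(w) == 22
        assert w.sum() == pytest.approx(1.0)
        assert (np.diff(w) < 0).all()


class TestTrueCurve:
    def test_log_rr_zero_at_mmt_and_u_shaped(self):
        c = TrueCurve(mmt=19.0, curv_cold=0.06, curv_heat=0.5)
        assert c.log_rr(19.0) == 0.0
        assert c.log_rr(25.0) > c.log_rr(21.0) > 0
        assert c.log_rr(5.0) > 0

    def test_true_heat_fraction_only_counts_days_above_mmt(self):
        c = TrueCurve(mmt=19.0)
        assert true_heat_fraction(c, np.full(100, 10.0)) == 0.0
        # single hot day at RR=2 among 100 days: h = 0.5/100
        from scipy.optimize import brentq
        t_hot = brentq(lambda x: c.log_rr(x) - np.log(2.0), 19.0, 60.0)
        t = np.full(100, 10.0)
        t[0] = t_hot
        assert true_heat_fraction(c, t) == pytest.approx(0.005)


class TestClimateModels:
    def test_anomaly_crosses_level_at_closed_form_year(self):
        cfg = SimConfig(warming_rate=0.3, warming_rate_jitter=0.0, anomaly_start=0.0,
                        n_model_years=80)
        _, anomaly = generate_model_series(cfg, 0, 0)
        # 0.03 °C/yr from 0: first year at +1.5 is year index 50
        years = anomaly.index.to_numpy()
        first = years[np.flatnonzero(anomaly.to_numpy() >= 1.5)[0]]
        assert first - cfg.start_year == 50

    def test_constant_bias_shifts_daily_mean(self):
        cfg = SimConfig(model_bias_mean=2.0, model_bias_sd=0.0, warming_rate=0.0,
                        warming_rate_jitter=0.0, temp_noise_sd=0.0,
                        n_model_years=2, n_years=2)
        daily, _ = generate_model_series(cfg, 0, 0)
        station = generate_temperature_series(cfg, 0)
        diff = daily.loc[station.index] - station
        assert np.allclose(diff, 2.0)

    def test_many_models_yield_distinct_series(self):
        cfg = SimConfig(n_models=31, n_model_years=2, n_years=2)
        series = [generate_model_series(cfg, 0, m)[0].to_numpy() for m in range(31)]
        assert len({s.tobytes() for s in series}) == 31

    def test_model_streams_independent_of_model_count(self):
        a = model_bias(SimConfig(n_models=3, seed=5), 1)
        b = model_bias(SimConfig(n_models=31, seed=5), 1)
        assert a == b
        assert model_warming_rate(SimConfig(seed=5), 0) != model_warming_rate(SimConfig(seed=5), 1)


class TestCovidAndMetadata:
    def test_covid_deaths_bounded_by_implied_total(self):
        cfg = SimConfig(n_locations=20, seed=61)
        tab = generate_covid_table(cfg)
        total = tab["crude_rate_per_1000"] * tab["population"] / 1000.0
        assert (tab["deaths_2020"] <= total).all()
        assert (tab["deaths_2021"] <= total).all()
        assert (tab[["deaths_2020", "deaths_2021"]] >= 0).all().all()

    def test_metadata_schema(self):
        md = generate_metadata(SimConfig(n_locations=5))
        assert list(md.columns) == ["location_id", "country", "region",
                                    "climate_class", "gdp_pc", "lon", "lat"]
        assert len(md) == 5
        assert md["lat"].between(-90, 90).all()
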