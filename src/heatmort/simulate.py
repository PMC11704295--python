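"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the data a multi-city temperature–mortality study would assemble:
per-location daily mortality counts and mean temperatures, location
metadata, per-climate-model daily temperature series with a warming trend
and a station bias, an annual global-mean temperature anomaly series per
model, and a country-level COVID-19 mortality table.

The mortality generator is the exact data-generating process the first-stage
estimator assumes: overdispersed Poisson counts whose log-mean is a baseline
plus a seasonal term plus a lag-distributed temperature effect.  The lag
weights are geometric and normalised to sum to one over lags 0..21, so the
true *cumulative* exposure–response curve equals the single-day curve
``f(T)`` exactly and is analytically known — which is what makes end-to-end
parameter-recovery checks possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrueCurve",
    "SimConfig",
    "true_heat_fraction",
    "generate_temperature_series",
    "generate_mortality_series",
    "generate_model_series",
    "generate_covid_table",
    "generate_metadata",
    "location_curve",
    "write_all_inputs",
]

LAG_MAX = 21

# sub-seed stream identifiers: SeedSequence([seed, STREAM, entity, ...])
_STREAM_STATION = 0
_STREAM_DEATHS = 1
_STREAM_CURVE = 2
_STREAM_MODEL = 3
_STREAM_COVID = 4
_STREAM_META = 5


@dataclass(frozen=True)
class TrueCurve:
    """Asymmetric U-shaped cumulative log-relative-risk curve.

    log RR(T) = c(d) * d^2  with  d = (T - mmt) / 10  and curvature blending
    smoothly (logistic in d) from ``curv_cold`` on the cold side to
    ``curv_heat`` on the hot side.  Zero at its minimum ``mmt``; smooth
    everywhere and steeper above the MMT, the shape cumulative
    temperature–mortality curves show empirically.
    """

    mmt: float = 19.0
    curv_cold: float = 0.15
    curv_heat: float = 0.5
    blend_width: float = 1.0

    def log_rr(self, temps) -> np.ndarray:
        t = np.asarray(temps, dtype=float)
        d = (t - self.mmt) / 10.0
        w = 1.0 / (1.0 + np.exp(-d / self.blend_width))
        return (self.curv_cold + (self.curv_heat - self.curv_cold) * w) * d**2


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with study-scale defaults.

    Temperatures are in °C, the warming rate in °C per decade, the
    global-mean anomaly relative to a preindustrial baseline.  The default
    anomaly at the start of the observation period is +1.0 °C (present-day
    conditions), so the +1 °C warming level falls at the start of the model
    record and +3 °C is reached within ``n_model_years`` at the default rate.
    """

    n_locations: int = 10
    n_years: int = 10
    start_year: int = 2000
    baseline_daily_deaths: float = 50.0
    seasonal_temp_mean: float = 15.0
    seasonal_temp_amplitude: float = 8.0
    temp_noise_sd: float = 2.0
    temp_ar1: float = 0.7
    true_curve: TrueCurve = field(default_factory=TrueCurve)
    lag_decay: float = 0.6
    heterogeneity_sd: float = 1.0
    overdispersion: float = 1.3
    mortality_seasonal_amplitude: float = 0.1
    n_models: int = 5
    model_bias_mean: float = 2.0
    model_bias_sd: float = 1.0
    warming_rate: float = 0.3
    warming_rate_jitter: float = 0.05
    anomaly_start: float = 1.0
    n_model_years: int = 90
    seed: int = 12345

    def __post_init__(self):
        if self.n_locations < 1 or self.n_years < 1 or self.n_models < 0:
            raise ValueError("counts must be positive")
        if self.baseline_daily_deaths <= 0:
            raise ValueError("baseline_daily_deaths must be positive")
        if not 0 <= self.temp_ar1 < 1:
            raise ValueError("temp_ar1 must lie in [0, 1)")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        for name in ("temp_noise_sd", "heterogeneity_sd", "model_bias_sd",
                     "seasonal_temp_amplitude", "lag_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self, stream: int, *entity: int) -> np.random.Generator:
        """Deterministic sub-stream: master seed + stream id + entity ids.

        Adding a location or model never perturbs earlier streams.
        """
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream, *entity]))


def _dates(start_year: int, n_years: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")


def _seasonal(dates: pd.DatetimeIndex, mean: float, amplitude: float, peak_doy: float = 196.0):
    doy = dates.dayofyear.to_numpy(dtype=float)
    return mean + amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter
    eps = rng.normal(0.0, sd, size=n)
    if n == 0:
        return eps
    # stationary start, then x[t] = phi * x[t-1] + eps[t]
    if phi > 0 and sd > 0:
        eps[0] = eps[0] / np.sqrt(1 - phi**2)
    return lfilter([1.0], [1.0, -phi], eps)


def lag_weights(decay: float, lag_max: int = LAG_MAX) -> np.ndarray:
    """Geometric lag weights normalised to sum to one over lags 0..lag_max."""
    w = decay ** np.arange(lag_max + 1, dtype=float)
    return w / w.sum()


def location_curve(config: SimConfig, location_id: int) -> TrueCurve:
    """The location's true curve: base curve perturbed by between-location
    heterogeneity (Gaussian shift of the MMT in °C, log-normal curvature)."""
    if config.heterogeneity_sd == 0:
        return config.true_curve
    rng = config.rng(_STREAM_CURVE, location_id)
    dm = rng.normal(0.0, config.heterogeneity_sd)
    dc = rng.normal(0.0, 0.15 * config.heterogeneity_sd, size=3)
    base = config.true_curve
    return TrueCurve(mmt=base.mmt + dm,
                     curv_cold=base.curv_cold * np.exp(dc[0]),
                     curv_heat=base.curv_heat * np.exp(dc[1]),
                     blend_width=base.blend_width * np.exp(dc[2]))


def true_heat_fraction(curve: TrueCurve, temps) -> float:
    """Annual heat-attributable fraction implied by the true curve over a
    temperature sample: mean over days of (RR-1)/RR on days above the MMT."""
    t = np.asarray(temps, dtype=float)
    rr = np.exp(curve.log_rr(t))
    af = np.where(t > curve.mmt, (rr - 1.0) / rr, 0.0)
    return float(af.mean())


def generate_temperature_series(config: SimConfig, location_id: int) -> pd.Series:
    """Daily mean temperature: seasonal sinusoid plus AR(1) noise."""
    dates = _dates(config.start_year, config.n_years)
    rng = config.rng(_STREAM_STATION, location_id)
    temps = _seasonal(dates, config.seasonal_temp_mean, config.seasonal_temp_amplitude)
    temps = temps + _ar1(len(dates), config.temp_ar1, config.temp_noise_sd, rng)
    return pd.Series(temps, index=dates, name="tmean")


def _log_mean(temps: pd.Series, config: SimConfig, curve: TrueCurve) -> np.ndarray:
    f = curve.log_rr(temps.to_numpy())
    w = lag_weights(config.lag_decay)
    # distributed-lag effect: sum_l w_l f(T_{t-l}); warm-up uses available lags
    lagged = np.convolve(f, w, mode="full")[: len(f)]
    doy = temps.index.dayofyear.to_numpy(dtype=float)
    seasonal = config.mortality_seasonal_amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
    return np.log(config.baseline_daily_deaths) + seasonal + lagged


def generate_mortality_series(temps: pd.Series, config: SimConfig, location_id: int) -> pd.Series:
    """Daily death counts from an overdispersed Poisson.

    The quasi-Poisson mean/variance structure (var = phi * mu) has no
    generative distribution, so counts are drawn NB1: negative binomial with
    mean mu and variance phi * mu, which degenerates to Poisson at phi = 1.
    """
    if len(temps) == 0:
        raise ValueError("temperature series is empty")
    curve = location_curve(config, location_id)
    mu = np.exp(_log_mean(temps, config, curve))
    rng = config.rng(_STREAM_DEATHS, location_id)
    phi = config.overdispersion
    if phi == 1.0:
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(mu / (phi - 1.0), 1.0 / phi)
    return pd.Series(counts, index=temps.index, name="deaths")


def model_warming_rate(config: SimConfig, model_id: int) -> float:
    """Per-model global warming rate (°C/decade), jittered deterministically."""
    if config.warming_rate_jitter == 0:
        return config.warming_rate
    rng = config.rng(_STREAM_MODEL, model_id, 0)
    return config.warming_rate * (1.0 + config.warming_rate_jitter * rng.normal())


def model_bias(config: SimConfig, model_id: int) -> float:
    rng = config.rng(_STREAM_MODEL, model_id, 1)
    return config.model_bias_mean + config.model_bias_sd * rng.normal()


def generate_model_series(config: SimConfig, location_id: int, model_id: int
                          ) -> tuple[pd.Series, pd.Series]:
    """One climate model's daily temperature at the location plus its annual
    global-mean anomaly series (°C above the preindustrial baseline).

    The daily series is a station-like draw (independent noise stream) plus a
    constant model bias plus a linear local warming trend that tracks the
    model's global anomaly; the anomaly series is exactly linear, so warming-
    level crossing times have a closed form.
    """
    if config.n_models < 1:
        raise ValueError("n_models must be >= 1")
    dates = _dates(config.start_year, config.n_model_years)
    rng = config.rng(_STREAM_MODEL, model_id, 2, location_id)
    temps = _seasonal(dates, config.seasonal_temp_mean, config.seasonal_temp_amplitude)
    temps = temps + _ar1(len(dates), config.temp_ar1, config.temp_noise_sd, rng)
    rate = model_warming_rate(config, model_id)
    years_elapsed = (dates.year.to_numpy() - config.start_year).astype(float)
    trend = rate / 10.0 * years_elapsed
    daily = pd.Series(temps + model_bias(config, model_id) + trend,
                      index=dates, name="tmean")
    years = np.arange(config.start_year, config.start_year + config.n_model_years)
    anomaly = pd.Series(config.anomaly_start + rate / 10.0 * (years - config.start_year),
                        index=pd.Index(years, name="year"), name="anomaly")
    return daily, anomaly


def generate_covid_table(config: SimConfig) -> pd.DataFrame:
    """Country-level COVID-19 deaths (2020, 2021), crude death rate per 1000
    and population; covid deaths never exceed the implied total mortality."""
    n = config.n_locations  # one country per location, matched by index
    rng = config.rng(_STREAM_COVID)
    population = rng.integers(2_000_000, 50_000_000, size=n)
    crude_rate = rng.uniform(7.0, 11.0, size=n)
    total = crude_rate * population / 1000.0
    frac_big = rng.uniform(0.05, 0.30, size=n)
    frac_small = frac_big * rng.uniform(0.3, 0.9, size=n)
    big_is_2021 = rng.random(n) < 0.5
    f2020 = np.where(big_is_2021, frac_small, frac_big)
    f2021 = np.where(big_is_2021, frac_big, frac_small)
    return pd.DataFrame({
        "country": [f"country_{i:03d}" for i in range(n)],
        "deaths_2020": np.round(f2020 * total).astype(int),
        "deaths_2021": np.round(f2021 * total).astype(int),
        "crude_rate_per_1000": crude_rate,
        "population": population,
    })


_REGIONS = ["North", "South", "East", "West"]
_CLIMATES = ["temperate", "continental", "arid", "tropical"]


def generate_metadata(config: SimConfig) -> pd.DataFrame:
    """Location metadata used as second-stage meta-predictors."""
    rng = config.rng(_STREAM_META)
    n = config.n_locations
    return pd.DataFrame({
        "location_id": [f"loc_{i:03d}" for i in range(n)],
        "country": [f"country_{i:03d}" for i in range(n)],
        "region": [_REGIONS[j] for j in rng.integers(0, len(_REGIONS), size=n)],
        "climate_class": [_CLIMATES[j] for j in rng.integers(0, len(_CLIMATES), size=n)],
        "gdp_pc": np.exp(rng.normal(9.5, 0.8, size=n)),
        "lon": rng.uniform(-180, 180, size=n),
        "lat": rng.uniform(-60, 70, size=n),
    })


def write_all_inputs(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every input CSV the pipeline reads; returns the path map.

    Schemas: daily (location_id, date, deaths, tmean); model (model_id,
    location_id, date, tmean); global mean (model_id, year, anomaly); covid;
    metadata.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    daily_rows, model_rows, anom_rows = [], [], []
    for i in range(config.n_locations):
        loc = f"loc_{i:03d}"
        temps = generate_temperature_series(config, i)
        deaths = generate_mortality_series(temps, config, i)
        daily_rows.append(pd.DataFrame({
            "location_id": loc, "date": temps.index.strftime("%Y-%m-%d"),
            "deaths": deaths.to_numpy(), "tmean": temps.to_numpy()}))
        for m in range(config.n_models):
            daily, anomaly = generate_model_series(config, i, m)
            model_rows.append(pd.DataFrame({
                "model_id": f"model_{m:02d}", "location_id": loc,
                "date": daily.index.strftime("%Y-%m-%d"), "tmean": daily.to_numpy()}))
            if i == 0:
                anom_rows.append(pd.DataFrame({
                    "model_id": f"model_{m:02d}", "year": anomaly.index,
                    "anomaly": anomaly.to_numpy()}))
    paths = {
        "daily": outdir / "daily_series.csv",
        "models": outdir / "model_series.csv",
        "global_mean": outdir / "global_mean.csv",
        "covid": outdir / "covid.csv",
        "metadata": outdir / "metadata.csv",
    }
    pd.concat(daily_rows).to_csv(paths["daily"], index=False, float_format="%.10g")
    pd.concat(model_rows).to_csv(paths["models"], index=False, float_format="%.10g")
    pd.concat(anom_rows).to_csv(paths["global_mean"], index=False, float_format="%.10g")
    generate_covid_table(config).to_csv(paths["covid"], index=False, float_format="%.10g")
    generate_metadata(config).to_csv(paths["metadata"], index=False, float_format="%.10g")
    return paths
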