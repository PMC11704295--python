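import numpy as np
import pandas as pd
import pytest

from heatmort.simulate import (SimConfig, generate_temperature_series,
                               generate_mortality_series, location_curve)
from heatmort.dlnm import DistributedLagModel


@pytest.fixture(scope="session")
def homogeneous_config():
    """One shared true curve, Poisson counts: the cleanest recovery setting."""
    return SimConfig(n_years=10, heterogeneity_sd=0.0, overdispersion=1.0, seed=20240501)


@pytest.fixture(scope="session")
def fitted_model(homogeneous_config):
    """A single first-stage fit reused across tests (fits are the slow part)."""
    cfg = homogeneous_config
    temps = generate_temperature_series(cfg, 0)
    deaths = generate_mortality_series(temps, cfg, 0)
    model = DistributedLagModel().fit(temps, deaths)
    return model, temps, deaths, location_curve(cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(977)


def make_daily(n=400, seed=5, mean=12.0, amp=7.0):
    """Small arbitrary daily temperature series for basis-level tests."""
    r = np.random.default_rng(seed)
    idx = pd.date_range("2010-01-01", periods=n, freq="D")
    doy = idx.dayofyear.to_numpy(dtype=float)
    t = mean + amp * np.cos(2 * np.pi * (doy - 196) / 365.25) + r.normal(0, 2, n)
    return pd.Series(t, index=idx)
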