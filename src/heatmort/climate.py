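"""Climate-model preparation: warming-level windows and bias correction.

Global warming levels (GWLs, e.g. +1.5 °C over the 1850–1900 preindustrial
baseline) are realised per climate model as the 20-year period whose
running-mean global anomaly first reaches the level; the window is centred
on its crossing year.  Daily model temperatures at a location are
bias-corrected to the station record by empirical quantile mapping over a
calibration period, by default stratified by calendar month to respect
seasonal bias structure, with constant-offset tails beyond the outermost
fitted quantiles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GwlWindow",
    "compute_gwl_windows",
    "QuantileMapper",
    "calibrate_quantile_map",
    "apply_bias_correction",
    "extract_nearest_gridcell",
]

WINDOW_YEARS = 20
DEFAULT_LEVELS = (1.0, 1.5, 2.0, 3.0)


@dataclass(frozen=True)
class GwlWindow:
    model_id: str
    level: float
    start_year: int
    end_year: int
    crossing_year: int

    def __post_init__(self):
        if self.end_year - self.start_year + 1 != WINDOW_YEARS:
            raise ValueError("warming-level window must span exactly 20 years")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def compute_gwl_windows(anomaly: pd.Series, levels=DEFAULT_LEVELS,
                        model_id: str = "") -> list[GwlWindow]:
    """20-year windows per warming level from an annual global-mean anomaly
    series (°C above preindustrial, indexed by year).

    The window for a level starts at the first year ``y`` such that the mean
    anomaly over ``y .. y+19`` reaches the level; the crossing year is the
    window centre (``start + 9``).  A level the series never reaches yields
    no window (with a warning).  Window start years are non-decreasing in
    level by construction.
    """
    anomaly = anomaly.sort_index()
    years = anomaly.index.to_numpy(dtype=int)
    if len(years) < WINDOW_YEARS:
        raise ValueError("anomaly series shorter than the 20-year window")
    if np.any(np.diff(years) != 1):
        raise ValueError("anomaly series has non-contiguous years")
    vals = anomaly.to_numpy(dtype=float)
    running = np.convolve(vals, np.ones(WINDOW_YEARS) / WINDOW_YEARS, mode="valid")
    out = []
    for level in levels:
        hit = np.flatnonzero(running >= level)
        if hit.size == 0:
            warnings.warn(f"model {model_id or '?'} never reaches +{level} °C; "
                          "no window returned", stacklevel=2)
            continue
        start = int(years[hit[0]])
        out.append(GwlWindow(model_id=model_id, level=float(level), start_year=start,
                             end_year=start + WINDOW_YEARS - 1,
                             crossing_year=start + WINDOW_YEARS // 2 - 1))
    return out


def windows_table(windows: list[GwlWindow]) -> pd.DataFrame:
    return pd.DataFrame([{"model_id": w.model_id, "level": w.level,
                          "start_year": w.start_year, "end_year": w.end_year,
                          "crossing_year": w.crossing_year} for w in windows])


class QuantileMapper:
    """Empirical quantile-mapping bias correction (scikit-learn style).

    Maps model quantiles to station quantiles at ``n_quantiles`` equally
    spaced probabilities (1..99% by default), linearly interpolating between
    fitted quantiles and applying a constant offset (the correction at the
    outermost quantile) beyond them, so the transform is monotone
    non-decreasing everywhere and never extrapolates the empirical map.

    With ``monthly=True`` (default) twelve separate maps are fitted, one per
    calendar month; the input series must then carry a DatetimeIndex.

    Fitted attributes: ``quantiles_model_``, ``quantiles_station_`` —
    dict keyed by month (0 for the annual map).
    """

    def __init__(self, n_quantiles: int = 99, monthly: bool = True):
        self.n_quantiles = n_quantiles
        self.monthly = monthly

    def get_params(self, deep: bool = True) -> dict:
        return {"n_quantiles": self.n_quantiles, "monthly": self.monthly}

    def set_params(self, **params) -> "QuantileMapper":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def probs_(self) -> np.ndarray:
        return 100.0 * np.arange(1, self.n_quantiles + 1) / (self.n_quantiles + 1)

    def _groups(self, series: pd.Series):
        if self.monthly:
            if not isinstance(series.index, pd.DatetimeIndex):
                raise ValueError("monthly quantile mapping needs a DatetimeIndex")
            return series.index.month
        return np.zeros(len(series), dtype=int)

    def fit(self, model_cal: pd.Series, station_cal: pd.Series) -> "QuantileMapper":
        """Calibrate on overlapping model and station daily series."""
        common = model_cal.index.intersection(station_cal.index)
        if len(common) == 0:
            raise ValueError("model and station calibration periods do not overlap")
        if len(common) < 365:
            raise ValueError("calibration period must cover at least one year")
        m = model_cal.loc[common]
        s = station_cal.loc[common]
        gm = self._groups(m)
        self.quantiles_model_, self.quantiles_station_ = {}, {}
        for g in np.unique(gm):
            sel = gm == g
            qm = np.percentile(m.to_numpy()[sel], self.probs_)
            qs = np.percentile(s.to_numpy()[sel], self.probs_)
            # enforce monotone non-decreasing maps under ties
            self.quantiles_model_[int(g)] = np.maximum.accumulate(qm)
            self.quantiles_station_[int(g)] = np.maximum.accumulate(qs)
        return self

    def _map_values(self, x: np.ndarray, g: int) -> np.ndarray:
        qm = self.quantiles_model_[g]
        qs = self.quantiles_station_[g]
        out = np.interp(x, qm, qs)
        lo, hi = x < qm[0], x > qm[-1]
        out[lo] = x[lo] + (qs[0] - qm[0])
        out[hi] = x[hi] + (qs[-1] - qm[-1])
        return out

    def transform(self, model_series: pd.Series) -> pd.Series:
        """Bias-correct a model series (calibration or projection period)."""
        if not hasattr(self, "quantiles_model_"):
            raise ValueError("QuantileMapper is not fitted")
        g = self._groups(model_series)
        x = model_series.to_numpy(dtype=float)
        out = np.empty_like(x)
        for grp in np.unique(g):
            sel = g == grp
            key = int(grp) if int(grp) in self.quantiles_model_ else 0
            out[sel] = self._map_values(x[sel], key)
        return pd.Series(out, index=model_series.index, name=model_series.name)

    def fit_transform(self, model_cal, station_cal):
        return self.fit(model_cal, station_cal).transform(model_cal)

    def to_dict(self) -> dict:
        return {"schema_version": 1, "n_quantiles": self.n_quantiles,
                "monthly": self.monthly,
                "quantiles_model": {k: v.tolist() for k, v in self.quantiles_model_.items()},
                "quantiles_station": {k: v.tolist() for k, v in self.quantiles_station_.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileMapper":
        qm = cls(n_quantiles=d["n_quantiles"], monthly=d["monthly"])
        qm.quantiles_model_ = {int(k): np.asarray(v) for k, v in d["quantiles_model"].items()}
        qm.quantiles_station_ = {int(k): np.asarray(v) for k, v in d["quantiles_station"].items()}
        return qm

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "QuantileMapper":
        return cls.from_dict(json.loads(Path(path).read_text()))


def calibrate_quantile_map(model_daily: pd.Series, station_daily: pd.Series,
                           n_quantiles: int = 99, monthly: bool = True) -> QuantileMapper:
    return QuantileMapper(n_quantiles=n_quantiles, monthly=monthly).fit(
        model_daily, station_daily)


def apply_bias_correction(mapper: QuantileMapper, model_daily: pd.Series) -> pd.Series:
    return mapper.transform(model_daily)


def _haversine(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def extract_nearest_gridcell(grid: pd.DataFrame, lon: float, lat: float) -> pd.Series:
    """Daily series of the grid point nearest (great-circle) to a location.

    ``grid`` is long-format with columns lon, lat, date, tmean.  Distance
    ties break lexicographically by (lat, lon) for determinism.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    pts = grid[["lon", "lat"]].drop_duplicates().sort_values(["lat", "lon"])
    d = _haversine(pts["lon"].to_numpy(), pts["lat"].to_numpy(), lon, lat)
    best = pts.iloc[int(np.argmin(d))]   # argmin returns the first = lexicographic winner
    sel = grid[(grid["lon"] == best["lon"]) & (grid["lat"] == best["lat"])]
    out = pd.Series(sel["tmean"].to_numpy(),
                    index=pd.DatetimeIndex(pd.to_datetime(sel["date"])), name="tmean")
    return out.sort_index()
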