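"""Comparison of projected heat mortality with COVID-19 mortality.

The COVID-19 mortality fraction ``c`` of a country is the ratio of its
COVID-19 deaths in the heavier of 2020/2021 to its total annual deaths
(crude death rate per 1000 x population / 1000).  The headline metric is
the number of years for cumulative heat-related deaths to equal one year
of COVID-19 deaths:

    Y = c / h

with ``h`` the annual heat-mortality fraction.  If 20% of one year's
deaths were COVID-19 and 1% of deaths each year are heat-related, heat
reaches the COVID-19 toll in 20 years.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impact import ImpactResult, summarize_cases

__all__ = [
    "CovidFraction",
    "covid_fraction",
    "covid_fractions_from_table",
    "years_to_equal",
    "build_comparison_table",
    "count_cities_within",
]

CASES = ("best", "average", "worst")


@dataclass(frozen=True)
class CovidFraction:
    country: str
    year_used: int
    covid_deaths: float
    total_deaths: float
    fraction: float


def covid_fraction(covid_2020: float, covid_2021: float, crude_rate_per_1000: float,
                   population: float, country: str = "") -> CovidFraction:
    """COVID fraction using the year with the higher COVID burden."""
    if population <= 0 or crude_rate_per_1000 <= 0:
        raise ValueError("population and crude death rate must be positive")
    if min(covid_2020, covid_2021) < 0:
        raise ValueError("negative COVID-19 death counts")
    total = crude_rate_per_1000 * population / 1000.0
    year_used, covid = (2021, covid_2021) if covid_2021 > covid_2020 else (2020, covid_2020)
    if covid > total:
        raise ValueError(f"COVID-19 deaths ({covid}) exceed implied total deaths "
                         f"({total}) for {country or 'country'}: inconsistent inputs")
    return CovidFraction(country=country, year_used=year_used, covid_deaths=float(covid),
                         total_deaths=float(total), fraction=float(covid / total))


def covid_fractions_from_table(covid: pd.DataFrame) -> dict[str, CovidFraction]:
    return {row.country: covid_fraction(row.deaths_2020, row.deaths_2021,
                                        row.crude_rate_per_1000, row.population,
                                        country=row.country)
            for row in covid.itertuples()}


def years_to_equal(c: CovidFraction | float, h: float) -> float:
    """Years of cumulative heat deaths equalling one year of COVID-19 deaths."""
    cf = c.fraction if isinstance(c, CovidFraction) else float(c)
    if cf < 0 or not np.isfinite(cf):
        raise ValueError("COVID fraction must be non-negative and finite")
    if h < 0 or not np.isfinite(h):
        raise ValueError("heat fraction must be non-negative and finite")
    if h == 0:
        warnings.warn("zero heat fraction: years-to-equal is infinite", stacklevel=2)
        return math.inf
    return cf / h


def build_comparison_table(impacts: list[ImpactResult],
                           covid: dict[str, CovidFraction],
                           metadata: pd.DataFrame,
                           threshold_years: float = 10.0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per location x level x case years-to-equal, plus city counts.

    The worst case uses the largest heat fraction (upper CI bound) and so
    gives the fewest years.  Counts tally locations with Y <= threshold
    (inclusive) per level and case.
    """
    loc2country = metadata.set_index("location_id")["country"].to_dict()
    unmatched = sorted({r.location for r in impacts} - set(loc2country))
    if unmatched:
        raise KeyError(f"locations missing from metadata: {unmatched}")
    missing_c = sorted({loc2country[r.location] for r in impacts} - set(covid))
    if missing_c:
        raise KeyError(f"countries missing from COVID table: {missing_c}")

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # h = 0 rows become inf, flagged in the table
        for r in impacts:
            cf = covid[loc2country[r.location]]
            cases = summarize_cases(r)
            for case in CASES:
                h = cases[case]
                rows.append({"location": r.location, "level": r.level, "case": case,
                             "heat_fraction": h, "covid_fraction": cf.fraction,
                             "years_to_equal": years_to_equal(cf, h),
                             "year_used": cf.year_used})
    table = pd.DataFrame(rows)
    counts = count_cities_within(table, threshold_years)
    return table, counts


def count_cities_within(table: pd.DataFrame, threshold_years: float = 10.0) -> pd.DataFrame:
    """Locations per level and case whose years-to-equal is <= the threshold."""
    hit = table[table["years_to_equal"] <= threshold_years]
    counts = (hit.groupby(["level", "case"])["location"].nunique()
              .reindex(pd.MultiIndex.from_product(
                  [sorted(table["level"].unique()), CASES],
                  names=["level", "case"]), fill_value=0)
              .rename("n_cities").reset_index())
    counts["threshold_years"] = threshold_years
    return counts


def render_years(y: float) -> str:
    """Whole-year rendering for reports: round half up; inf stays inf."""
    if math.isinf(y):
        return "inf"
    return str(int(math.floor(y + 0.5)))
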