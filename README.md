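# heatmort

Two-stage temperature–mortality modelling, projection of heat-attributable
deaths at global warming levels (GWLs), and the *years-to-equal* comparison
of projected heat mortality against COVID-19 mortality burdens.

## Who this is for

Environmental epidemiologists and climate-impact researchers who want a
tested, reproducible pipeline for the standard two-stage design: city-level
quasi-Poisson time-series regression with distributed-lag non-linear models
(DLNM), multivariate meta-regression with best linear unbiased predictions
(BLUPs), quantile-mapping bias correction of climate-model temperatures,
and Monte-Carlo empirical confidence intervals for heat-attributable
mortality. Because daily mortality databases and climate-model archives are
restricted or bulky, the package ships a synthetic-data generator with
analytically known ground truth, so every stage — and the pipeline end to
end — is testable without any download.

## The model

**First stage.** For each location, daily death counts are modelled as
overdispersed Poisson with

log μ<sub>t</sub> = α + cb(T<sub>t</sub>, …, T<sub>t−21</sub>) + ns(t; 8 df/year) + DOW<sub>t</sub>

where `cb` is the DLNM cross-basis: natural cubic spline in temperature
(knots at the 10th/75th/90th percentiles) ⊗ natural cubic spline in lag
(0–21 days, log-spaced knots). The fitted surface is reduced to the
cumulative exposure–response curve log RR(T), centred at the minimum
mortality temperature (MMT).

**Second stage.** Location-specific reduced coefficients β<sub>i</sub> are
pooled by REML multivariate meta-regression, β<sub>i</sub> ~ N(Θᵀx<sub>i</sub>, Ψ + S<sub>i</sub>), with
meta-predictors (region, climate class, log GDP per capita, mean/range of
temperature), and BLUPs shrink each location toward its meta-prediction.

**Projection.** Per climate model, 20-year GWL windows (+1, +1.5, +2, +3 °C
over 1850–1900) are located from the 20-year running mean of the global
anomaly; daily model temperatures are bias-corrected to the station record
by monthly empirical quantile mapping. For days with T > MMT the
attributable fraction is AF = (RR−1)/RR and the annual heat-mortality
fraction is h = Σ AF · deaths / total deaths. Uncertainty: 1000 Monte-Carlo
coefficient draws × model windows pooled into empirical 95% intervals
(best/average/worst cases).

**Comparison.** With c the national COVID-19 mortality fraction (deaths in
the heavier of 2020/2021 over crude-rate × population), the headline metric
is **Y = c / h** — years of cumulative heat-related deaths equal to one year
of COVID-19 deaths.

## Worked example

```python
from heatmort import covid_fraction, years_to_equal

cf = covid_fraction(covid_2020=2000, covid_2021=1500,
                    crude_rate_per_1000=10.0, population=1_000_000)
print(cf.fraction, cf.year_used)   # 0.2 2020
print(years_to_equal(cf, 0.01))    # 20.0
```

A country with 10,000 total deaths per year and 2,000 COVID-19 deaths in its
worst year has a COVID-19 mortality fraction of 20%; a city where 1% of
annual deaths are heat-related needs 20 years of heat mortality to match
that single year.

Full synthetic pipeline from a shell:

```bash
heatmort run-all --seed 42 --outdir demo_run
```

writes `demo_run/comparison.csv` with one row per location × GWL × case,
e.g. (seed 42, default 10-location synthetic configuration)

```
location  level  case     heat_fraction  covid_fraction  years_to_equal
loc_000   1.0    average  0.0280         0.1382          4.93
loc_000   3.0    average  0.0509         0.1382          2.71
```

— 2.8% of this synthetic city's deaths are heat-related at +1 °C, so it
needs ~4.9 years of heat mortality to match one pandemic year; at +3 °C the
heat fraction grows to 5.1% and the metric drops to ~2.7 years — plus
`city_counts.csv` (locations with Y ≤ 10 years per level and case) and a
`manifest.json` with the config hash and seed for byte-identical reruns.

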