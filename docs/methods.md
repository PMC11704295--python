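# Methods

## Scope

The package implements the standard two-stage design for multi-city
temperature–mortality analysis and its projection to global warming levels
(GWLs), together with a comparison metric against COVID-19 mortality and a
synthetic-data generator that makes the whole chain testable with known
ground truth. It does not model adaptation, population change, demographic
structure, cold-attributable mortality, or heat–COVID interaction, and it
reads per-location extracted climate series (long-format CSV), not native
gridded archives.

## First stage: quasi-Poisson DLNM

Daily deaths are regressed on a distributed-lag non-linear cross-basis of
daily mean temperature, a natural cubic spline of time, and day-of-week
indicators, with a log link and Pearson-estimated overdispersion φ
(standard errors scale by √φ). Defaults and the reasons for them:

- **Exposure basis**: natural cubic spline, interior knots at the
  10th/75th/90th percentiles of the location's observed temperatures,
  boundary knots at the observed min/max. Dimension 4, no intercept (the
  regression carries its own).
- **Lag basis**: natural cubic spline over lags 0–21 days with an
  intercept. The three lag knots are spaced evenly on the log scale *up to
  the maximum lag* (21^{1/3}, 21^{2/3}, 21); the last knot coincides with
  the upper boundary, so the basis has dimension 4 and the cross-basis
  4 × 4 = 16 columns. Linear spacing is available
  (`BasisSpec(lag_knot_scale="linear")`).
- **Natural splines** are built as cubic B-splines projected on the null
  space of the boundary second-derivative constraints; without an
  intercept the first B-spline column is dropped *before* constraining, so
  the basis plus a constant spans the full natural-spline space. Beyond the
  boundary knots the basis continues linearly (first-order Taylor at the
  boundary), which is exactly the log-linear extrapolation used when
  projection-period temperatures exceed the observed range.
- **Time spline**: round(8 × years) total df, knots at equally spaced
  dates; leap days count as day fractions of a 365.25-day year.
- **Warm-up**: the first 21 rows have incomplete lag windows and are
  dropped from the likelihood rather than padded with fabricated history.
  Rows with missing deaths or temperature are likewise dropped.
- **Fitting**: IRLS via statsmodels GLM (Poisson family, Pearson-X2
  scale), max 100 iterations.
- **Reduction**: with cross-basis columns ordered exposure-major, the
  cumulative curve is β_red = (I ⊗ s)ᵀ β with s the lag-basis column sums;
  the covariance maps through the same operator.
- **MMT search**: 0.1 °C grid between the 1st and 99th percentiles of the
  observed temperatures (avoids boundary artefacts); exact ties break
  toward the observed median.

## Second stage: REML meta-regression and BLUPs

β_red,i ~ N(Θᵀx_i, Ψ + S_i). Ψ is estimated by REML with a Cholesky
parameterisation (log-diagonal), L-BFGS-B on the profiled objective with a
Nelder-Mead polish, initialised at 0.1 × the average within-location
covariance; the returned solution is never worse than the initialisation.
Meta-predictors are one-hot region and climate-class indicators (first
level dropped, constant columns removed), standardised log GDP per capita
and standardised mean/range of observed temperature. With few locations the
pipeline keeps at most n−2 predictor columns, dropping from the right of
the design. BLUPs use β_blup,i = Θᵀx_i + Ψ(Ψ+S_i)⁻¹(β_i − Θᵀx_i); their
covariance combines the conditional covariance S_i(Ψ+S_i)⁻¹Ψ with
propagated fixed-effect uncertainty. The MMT is re-found on each BLUP
curve. Because empirical-Bayes intervals ignore the sampling error of Ψ̂,
confidence intervals on pooled and BLUP quantities use t quantiles at the
residual df (n − q, exposed as ``df_resid_``), the standard small-sample
adjustment for meta-analysis; normal quantiles visibly undercover with ten
locations (see Validation).

## Climate preparation

- **GWL windows**: for each model, the window for level L is the first
  20-year span whose mean global anomaly (vs 1850–1900) reaches L; the
  crossing year is the window centre. Start years are non-decreasing in L
  by construction; models that never reach a level yield a warning and no
  window.
- **Quantile mapping**: 99 percentile pairs (1–99%) between model and
  station over the calibration overlap, by default fitted separately per
  calendar month to respect seasonal bias structure. Between fitted
  quantiles values interpolate linearly; beyond the outermost quantile a
  constant offset (the correction at that quantile) applies, so the map is
  monotone and never extrapolates the empirical relationship. Ties in the
  fitted quantiles are made non-decreasing by cumulative max.
- **Grid extraction**: nearest neighbour by great-circle (haversine)
  distance; exact ties break lexicographically by (lat, lon).

## Impact projection

Attribution uses the forward formulation on the cumulative curve:
AF_t = (RR_t − 1)/RR_t for days with T_t above the MMT, 0 otherwise, and
AF is clamped at 0 when a coefficient draw makes RR < 1 above its MMT
(attribution counts heat excess only; this also keeps the heat fraction in
[0, 1)). Annual attributable deaths divide the 20-year window sum by 20;
the heat fraction divides by baseline × 365.25 and is therefore invariant
to the baseline, which is held constant at the location's observed mean
daily deaths (no adaptation or population change). Monte-Carlo empirical
intervals draw n_sim = 1000 coefficient vectors from N(β_blup, V_blup)
(eigenvalue square root, negative eigenvalues truncated at 0), re-find the
MMT per draw, evaluate every model window at the level, and pool all
draw × model values into one empirical distribution; best/average/worst
cases are its 2.5/50/97.5 percentiles. Fixed-MMT mode is available.

## Comparison metric

c = max(COVID deaths 2020, 2021) / (crude rate × population / 1000), the
year recorded; Y = c / h, reported as a real number (+∞ sentinel with a
warning when h = 0). Whole-year rendering rounds half up and happens only
in report rendering. City counts use an inclusive threshold (Y ≤ 10 years
by default). Country-level c applies to every city of the country.

## Synthetic-data generator

The generator is the estimator's own data-generating process plus the
climate-side artefacts the pipeline must undo:

- **Temperature**: seasonal sinusoid (mean 15 °C, amplitude 8 °C, peak
  mid-July) plus stationary AR(1) noise (φ = 0.7, innovation sd 2 °C).
  Real calendars with leap days.
- **True cumulative curve**: smooth asymmetric U,
  log RR = c(d)·d² with d = (T − MMT)/10 and c(d) blending logistically
  from 0.15 (cold side) to 0.5 (hot side) over the d scale. At the default
  climate this gives RR ≈ 1.24 at the 1st percentile and ≈ 1.38 at the
  99th, with the MMT (19 °C) near the 75th percentile — the shape and
  magnitudes empirical cumulative curves show. The blend is gradual
  because a 4-df natural spline cannot track abrupt curvature changes;
  a kinked truth would make every recovery check measure basis
  approximation error instead of estimator quality.
- **Mortality**: NB1 counts (variance φμ, Poisson at φ = 1, default
  φ = 1.3) with log-mean = log(baseline) + winter-peaking seasonal term +
  Σ_l w_l f(T_{t−l}), geometric lag weights normalised to sum to 1 over
  lags 0–21 — so the true cumulative curve *is* f, analytically.
  Baseline 50 deaths/day (≈ a 2-million city): large enough to identify
  the MMT within 1 °C, small enough that within-location uncertainty
  remains visible to the second stage.
- **Heterogeneity**: per-location Gaussian MMT shift (sd 1 °C) and
  log-normal jitter (sd 0.15) of both curvatures and the blend width —
  four independent degrees of freedom, so the induced coefficient
  covariance is full rank.
- **Climate models**: station-like daily series + constant per-model bias
  (N(2, 1) °C) + linear local warming equal to the model's global anomaly
  trend (0.3 °C/decade ± 5% per-model jitter, anomaly +1.0 °C at the start
  of the record, 90 model years). Anomaly series are exactly linear, so
  GWL crossings have closed forms.
- **COVID tables**: populations 2–50 M, crude rates 7–11/1000, COVID
  fractions 5–30% in the heavier year; deaths never exceed implied totals.
- **Sub-seeding**: every stream derives from SeedSequence([master, stream,
  entity…]); adding a location or model never perturbs existing series.

What the generator does *not* emulate: spatial correlation between
locations, mortality displacement (harvesting), humidity or other
co-exposures, reporting artefacts, demographic drift, non-stationary
variance in model output. Passing recovery checks therefore shows the
estimator chain is correct under its own assumptions, not that those
assumptions hold in any particular real dataset.

## Validation battery and problem sizes

`heatmort.validation` (driven by `scripts/acceptance.py` and the test
suite) measures, per master seed:

- the worked example of the metric (20% / 1% → 20 years, exact);
- cross-basis vs a brute-force double-sum oracle on random ≤ 100-day
  series, and reduction vs summed lag-specific predictions (≤ 1e-10);
- BLUP coverage: 5 replicate studies of 10 locations × 10 years; pointwise
  95% CIs (t quantile, df = n − q) vs the true curve on a 40-point grid
  between the 5th and 95th temperature percentiles, pooled (2000 points).
  A single replicate has seed spread of ±5 points, which pooling averages
  out;
- MMT recovery: median |error| over 100 single-location replicates;
- quantile-map closure at the fitted quantiles (by construction ≤ 1e-6;
  quantiles *of* the corrected series match only up to order-statistic
  interpolation error) and removal of a +2 °C synthetic bias within
  0.1 °C (low-noise configuration so AR(1) mean wander does not mask the
  check);
- GWL windows vs closed form and an exhaustive 20-year-mean scan;
- end-to-end recovery: 40 replicate studies of 3 locations × 3 models
  (homogeneous true curves; with ±1 °C between-location heterogeneity and
  3 locations, per-location recovery is not identified — BLUPs must
  shrink), comparing the pooled heat fraction per GWL with the true curve
  integrated over station temperatures shifted by the window's mean
  anomaly above the calibration period. The median relative error carries
  a small positive plug-in bias (h is convex in the coefficients), well
  inside the 10% tolerance; the first replicate also runs 200-draw
  Monte-Carlo intervals and checks Y_worst ≤ Y_average ≤ Y_best on every
  row;
- Monte-Carlo degeneracy: zero covariance + one model → zero-width eCI.

## Known limitations

- REML with a Cholesky parameterisation can sit at a boundary (singular
  Ψ̂) in small studies; BLUPs then over-shrink along the null directions.
- The linear log-RR extrapolation beyond observed temperatures
  underestimates a truth whose curvature keeps growing; at +3 °C windows
  this partially offsets the plug-in bias.
- The quantile map assumes the model's bias structure is stationary
  between calibration and projection periods (per month, per quantile).
- Baseline mortality is frozen at the observed mean; h and Y scale
  directly with any future change in total mortality.
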