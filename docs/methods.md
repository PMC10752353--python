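# Methods

`agriair` estimates how surface ozone, fine particulate matter (PM2.5)
and temperature extremes affect agricultural total factor productivity
(TFP), using a county-year panel design in which pollution exposure is
instrumented by wind direction. This note documents the models, the
synthetic data-generating process the package is validated against, the
numerical choices, and the limits of what the tests show.

## The outcome model and its identification

The structural model is log-linear in annual exposures:

    log TFP_it = β_O3·Ozone_it + β_PM·PM2.5_it + X_it'γ + α_i + λ_t + u_it

where `i` indexes counties and `t` years, `Ozone_it` is the annual (or
winter/nonwinter, or a cumulative-index) measure of MDA8 ozone in ppb,
`PM2.5_it` is in μg/m³, `X_it` collects weather controls — fractional
day counts per 5 °C temperature bin (the top bin, days at or above
35 °C, is the heat-extremes regressor) plus linear and quadratic terms
of cumulative precipitation, sunshine hours, mean relative humidity,
air pressure and wind speed — and `α_i`, `λ_t` are county and year
fixed effects. Coefficients are semi-elasticities: ×100 they read as
percent TFP change per unit of exposure.

Pollution is not randomly assigned — agriculture itself emits pollution
precursors, and exposure is measured with error — so least squares is
biased. The instruments exploit that wind direction moves pollution but
has no direct productivity channel: for spatial groups g (k-means
clusters of county coordinates) and 90° wind quadrants a ∈ {0, 1, 2}
(the quadrant [270°, 360°) is the reference), the first stage is

    Pollution_it = Σ_g Σ_a π_ag · 1[G_i = g] · WD_it^a + X_it'γ + α_i + λ_t + σ_it

with `WD_it^a` the number of days in the year whose daily mean wind
direction falls in quadrant a. Group-specific responses π_ag give 3·K
instruments; both pollution variables are instrumented jointly.

Estimators: two-way fixed effects are absorbed by alternating demeaning
(tolerance 1e-10; one sweep suffices on balanced panels), then OLS,
2SLS or LIML is applied as a κ-class estimator (κ = 0, 1, or the
minimum-eigenvalue LIML κ ≥ 1). Standard errors are cluster-robust at
the county level with the G/(G−1)·(N−1)/(N−k) small-sample factor, k
counting absorbed fixed-effect parameters. Instrument strength is
diagnosed with the cluster-robust Kleibergen–Paap rank Wald F (the rank
statistic divided by the instrument count, reducing to the robust
first-stage Wald F with one endogenous regressor and one instrument)
and the Cragg–Donald F alongside, since software conventions for the
robust weighting differ.

## Exposure metrics

- **MDA8**: the maximum over the 17 complete same-day 8-hour windows
  (start hours 0–16) of the running mean; a day needs ≥ 18 valid hours
  and a window ≥ 6 of 8. Same-day windows avoid any cross-midnight
  dependency; regulatory variants that let windows span midnight differ
  slightly and can be compared externally.
- **Unit conversion**: μg/m³ ↔ ppb through the ideal-gas molar volume
  R·T/P (defaults 298 K, 1013 hPa; ozone molar mass 48 g/mol). The WHO
  peak-season guideline of 60 μg/m³ is 30.6 ≈ 31 ppb.
- **Hourly reconstruction**: monthly mean MDA8 plus a region-month
  peak/nonpeak ratio expand into hourly series in which the 8 peak
  hours of every day of the month equal the monthly MDA8 and the 16
  nonpeak hours equal MDA8/ratio. Applying the MDA8 operator to the
  reconstruction returns the input exactly (for ratio ≥ 1), which is
  the self-consistency test.
- **Cumulative indices**: AOT40 = Σ(C_h − 40) over hours above 40 ppb;
  SUM06 = ΣC_h over hours above 60 ppb (both strict inequalities, ppb
  scale); W126 = ΣC_h·[1 + 4403·exp(−126·C_h)]^(−1) with C_h in ppm —
  the sigmoid constants are only dimensionally coherent on the ppm
  scale (the EPA convention), so ppb input is converted internally.
  Under the reconstruction rule each annual index collapses to a closed
  form over the 12 monthly levels, which the generator uses directly;
  the tests verify the closed form against the full hourly expansion.

## Weather processing

Fractional day counts per temperature bin come from the single-sine
method: within a day, T(t) = m + A·sin(2πt) with m the midpoint and A
half the diurnal range, so the fraction of the day below a threshold c
has the arcsine closed form ½ + arcsin((c−m)/A)/π. Bins are half-open,
first bin (−∞, 0 °C), last [35 °C, ∞); fractions sum to one by
construction and are checked against a 10,000-step discretization of
the sinusoid. Station-to-county interpolation is inverse-distance
weighting over great-circle distances within a 200 km radius with
power 1 (configurable); a literal reading of "distance as the weight"
would upweight far stations, so the inverse convention is used. County
grouping is k-means (k-means++ initialization, 10 restarts, fixed
seed) on (longitude, latitude).

## TFP from production functions

Four estimators of county-year TFP from aggregate output value and four
inputs (cropland, labor, fertilizer, machinery), all pooled fits:
Cobb–Douglas and translog by (restricted) least squares, with constant
returns imposed as Σβ_j = 1 (and, for the translog with the half-square
column convention, β_jj + Σ_{k≠j}β_jk = 0 per input); and a
Cobb–Douglas stochastic frontier with normal noise and half-normal
inefficiency, fitted by maximum likelihood over log-variances from an
OLS start plus four seeded perturbations (frontier likelihoods can be
multimodal at small n). CRS for the frontier is imposed by estimating
in per-cropland form. Technical efficiency is the Jondrow conditional
mean exp(−E[u|ε]); a boundary solution σ_u → 0 is reported as the
least-squares limit. The TFP index is output over the slope-only
frontier prediction, normalized to a unit sample geometric mean — a
documented convention, as index-number alternatives (Törnqvist/Fisher)
are out of scope. Labor productivity (output per worker) is the
companion partial measure.

## The synthetic data-generating process

The generator emulates the study conditions so that every stage has a
known truth. Defaults (the study conditions, fixed once):

- 400 counties × 14 years (first year 2002), 8 spatial wind-regime
  groups from k-means on uniformly scattered coordinates.
- Daily weather per county-year: seasonal sinusoid temperatures with
  latitude-dependent means (so hot days concentrate in warm counties;
  the sample mean is ≈ 29 days ≥ 35 °C per county-year), exponential
  precipitation, truncated-normal sunshine/humidity/pressure/wind
  speed.
- Daily wind direction is von Mises with concentration 0.8 around a
  mean that depends on the county's group, drifts by (group, year)
  with a 40° standard deviation, and carries a 12° county offset. The
  drift plus day-level sampling noise create the within-county
  variation in quadrant day counts that makes the instruments relevant.
- Pollution: monthly ozone = seasonal base (38 + 12·cos, peaking in
  July) + group-specific wind-bin responses π_ag (scale 0.12 ppb per
  bin-day; separate draws for winter and nonwinter months, so the
  seasonal specification stays identified) + weather coupling + a
  county-year shock (sd 2.5 ppb); PM2.5 analogous (shock sd 8 μg/m³).
  Annual, winter and nonwinter means and the cumulative indices (peak
  ratio 1.6) derive from the monthly values.
- Endogeneity: the pollution shocks correlate with the outcome error at
  ρ (default 0.5), implemented as shock = ρ·(σ_shock/σ_u)·u + √(1−ρ²)·z,
  so the correlation is exact in population. With ρ = 0.5 the OLS
  ozone coefficient is biased toward zero by ≈ +0.008 while 2SLS is
  unbiased to Monte Carlo precision — the qualitative OLS/IV contrast
  of the real-data design.
- Outcome: log TFP is built exactly from the configured β_O3 (−0.0224
  per ppb annual MDA8), β_PM (−0.0092), β_hot (−0.0050), γ (sunshine
  5e-4 per hour, smaller terms elsewhere, zero quadratics), county FE
  (sd 0.30), year FE (sd 0.10) and noise (sd 0.15). An alternative
  `effect_basis="nonwinter"` puts the whole ozone effect on nonwinter
  exposure with a zero winter effect.
- Production records back the log TFP series out through a Cobb–Douglas
  technology (elasticities 0.25/0.30/0.25/0.20) so the TFP stage can be
  exercised end to end.
- All randomness flows from the config seed through one stream with a
  fixed draw order (weather cube first, then panel-level draws);
  identical configs give byte-identical panels, and per-county-year
  daily series are slices of the same realization.

Calibration note: the wind-effect scale and von Mises concentration
were set so the first-stage Kleibergen–Paap F sits comfortably above
the >10 relevance regime (median ≈ 165 across replicates at the
default size) — strong instruments keep the many-instrument bias of
2SLS below one Monte Carlo standard error of the 200-replicate mean,
which is what the recovery check requires.

What the generator does not emulate: real spatial pollution fields or
their spatial autocorrelation, serially correlated TFP shocks,
unbalanced panels, measurement error in exposures, or any
general-equilibrium feedback. Passing tests therefore certify the
estimators and pipeline on data satisfying the model's assumptions,
not the substantive real-data findings.

## Counterfactual scenarios

A scenario perturbs one driver: fix each county at its reference-year
value, cap at a threshold (e.g. the 31 ppb WHO guideline for ozone, or
PM2.5 at 35 μg/m³ — the cap rule is the declared operationalization; a
proportional national cut can be expressed by rescaling the column
before capping), or shift daily temperatures uniformly (e.g. +2 °C),
re-deriving every temperature bin from the shifted days. County-year
percent TFP changes use the exact log-linear form 100·(exp(β'Δx) − 1),
with the first-order 100·β'Δx reported alongside; only coefficient
columns that changed contribute. National aggregates weight county
changes by output value; the 95% band is the delta method holding Δx
fixed and propagating the coefficient cluster-robust covariance (a
parametric bootstrap cross-check sits in the tests). Exposure-model
uncertainty is not propagated.

## Placebo inference

Falsification re-estimates the model on panels whose
pollution–productivity pairing is broken, and locates the baseline
estimate in the placebo distribution. Two designs:

- **Pollution-block permutation** (default): the exposure columns and
  the wind-bin counts move together across rows (globally or within
  strata). Moving the instruments with the exposures keeps every
  placebo fit strongly identified; permuting exposures alone would
  leave the placebo fits weakly identified and heavy-tailed. This is
  the falsification device: under the default effect process the
  baseline falls far outside the placebo range.
- **Outcome permutation within counties** (`target="outcome"`,
  stratified by county): log TFP is shuffled across years within each
  county, leaving all regressors aligned with their rows. Because the
  outcome carries little row-structured signal beyond its fixed
  effects, this placebo distribution matches the null sampling
  distribution and is the right tool for calibration-style checks.
  (The pollution-block variant is *not* calibration-grade: permuted
  pollution carries county-level means and weather-driven components
  that fixed effects and controls no longer absorb, which widens the
  placebo denominator and narrows the estimates.)

Stratified pollution permutation within (group, year) cells is also
provided; with group-level exposure structure it retains the common
component of the association by construction, so its placebo estimates
shrink toward a fraction of the baseline rather than zero.

## Numerical choices

- Design columns are norm-equilibrated before solving normal equations
  (quadratic weather terms otherwise push the condition number past
  what double precision tolerates); coefficients and covariances are
  rescaled back.
- Instrument collinearity is resolved by a sequential QR pass in fixed
  group-major, bin-minor order at relative tolerance 1e-10, so the
  retained set is deterministic.
- The LIML κ comes from the generalized eigenvalue problem on the
  control-partialled [y, endogenous] block and is floored at 1.
- The within transform iterates to a 1e-10 maximum group mean;
  singleton observations in any absorbed level are dropped iteratively
  before estimation; rows with missing estimation columns are removed
  listwise with a logged count.
- The stochastic frontier reparameterizes to log-variances; σ_u below
  1e-4 of the residual scale is treated as the OLS boundary.
- Scenario aggregation requires nonnegative, not-all-zero weights; the
  temperature rule requires the daily arrays and errors otherwise.

## Problem sizes used in the checks

The recovery experiment uses 200 panels at the default 400 × 14 size;
the frontier recovery uses 100 replicates at n = 2,000 with σ_v = 0.1,
σ_u = 0.3; placebo checks use 200 replicates on an 80 × 8 panel for the
effect branch and 20 meta-replicates × 100 permutations on 40 × 6
panels for the null branch; desk-scale examples elsewhere use 30–80
counties. These sizes were chosen so the full suite reproduces the
statistical claims at Monte Carlo precision on a single CPU.

## Panel CSV column dictionary

One row per county-year (UTF-8, header row, empty string for missing):

| column | meaning |
|---|---|
| `county`, `year` | identifiers; `county` is the 0-based county index, `year` a calendar year |
| `group` | spatial wind-regime group label (1..K) |
| `lon`, `lat` | county centroid coordinates (degrees) |
| `weight` | county output value used for national aggregation |
| `log_tfp`, `tfp` | outcome: log TFP and its level |
| `ozone_annual`, `ozone_winter`, `ozone_nonwinter` | mean MDA8 ozone, ppb (winter = months 12, 1, 2) |
| `aot40`, `sum06`, `w126` | annual cumulative ozone indices (ppb·h, ppb·h, ppm·h) |
| `pm25` | annual PM2.5, μg/m³ |
| `wd_bin_0` … `wd_bin_3` | days with mean wind direction in [0,90), [90,180), [180,270), [270,360) |
| `tbin_lt0`, `tbin_0_5`, …, `tbin_ge35` | fractional day counts per 5 °C temperature bin |
| `precip`, `sunshine` | annual totals (mm, hours) |
| `humidity`, `pressure`, `wind_speed` | annual means (%, hPa, m/s) |
| `*_sq` | squares of the five continuous controls |

## Known limitations

- The four TFP estimators are pooled cross-section fits; fixed effects
  inside the production function and time-varying inefficiency are not
  modeled.
- The Kleibergen–Paap implementation follows the orthonormalized-score
  construction; other software may apply slightly different
  small-sample factors, which is why the Cragg–Donald statistic is
  reported alongside.
- Delta-method scenario bands treat exposures as fixed and propagate
  coefficient uncertainty only.
- The pipeline's caching keys on config hash and output checksums; it
  does not track code changes.
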