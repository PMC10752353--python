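# agriair

Panel econometrics of air pollution and agricultural productivity:
ozone exposure metrics, production-function TFP estimation, a
wind-direction-instrumented fixed-effects IV estimator, counterfactual
exposure scenarios, and permutation placebo inference — validated end
to end against a synthetic county-year panel generator with known
ground truth.

## The problem

Surface ozone damages vegetation, and fine particulates (PM2.5) cut the
solar radiation reaching crops; both plausibly depress agricultural
**total factor productivity** (TFP) — aggregate output per unit of
aggregate input — beyond what single-crop yield studies capture. But a
regression of TFP on pollution is confounded: agriculture emits
pollution precursors, and exposures are measured with error. The
identification strategy here instruments pollution with **wind
direction**: the number of days per year a county's daily mean wind
blows from each 90° quadrant shifts local pollution (by moving it in
from, or out toward, upwind regions) but has no direct productivity
channel.

The estimating equations are the two-way fixed-effects panel model

```
log TFP_it = β_O3·Ozone_it + β_PM·PM2.5_it + X_it'γ + α_i + λ_t + u_it
Pollution_it = Σ_g Σ_{a=0}^{2} π_ag·1[G_i=g]·WD_it^a + X_it'γ + α_i + λ_t + σ_it
```

with county and year fixed effects, a flexible weather-control set
X_it (5 °C temperature-bin day counts from a single-sine interpolation
of daily min/max, plus linear and quadratic precipitation, sunshine,
humidity, pressure and wind speed), spatial groups G_i from k-means on
county coordinates, and cluster-robust (county) inference. β are
semi-elasticities: ×100, percent TFP change per ppb of ozone, per
μg/m³ of PM2.5, or per day at or above 35 °C.

The package provides OLS / 2SLS / LIML on this design with
Kleibergen–Paap and Cragg–Donald first-stage diagnostics; MDA8 and
the AOT40 / SUM06 / W126 cumulative ozone indices (with the
monthly-MDA8 hourly reconstruction used when hourly data are
unavailable); four TFP estimators (translog and Cobb–Douglas, with and
without constant returns, and a normal/half-normal stochastic
frontier); scenario projections with delta-method bands; and placebo
permutation tests. A seeded synthetic-panel generator with a tunable
endogeneity dial supplies ground truth for every stage.

## Worked example

```python
from agriair import (SynthConfig, generate_panel, PanelIVModel,
                     ScenarioSpec, project)

cfg = SynthConfig(n_counties=100, n_years=14, seed=7)   # truth: β_O3 = −0.0224
panel, truth = generate_panel(cfg)

fit = PanelIVModel.from_panel(panel).fit("2sls")
print(fit.summary(top=3))
```

```
Panel 2SLS — outcome 'log_tfp'
  N = 1400, clusters = 100, absorbed FE params = 113
  instruments = 24, KP F = 182.6285, Cragg–Donald F = 95.2570
  kappa = 1.000000
                                 coef         se        t     [0.025     0.975]
  ozone_annual                -0.0222     0.0010   -22.68    -0.0241    -0.0202
  pm25                        -0.0089     0.0004   -19.91    -0.0098    -0.0080
  tbin_lt0                     0.0013     0.0067     0.19    -0.0120     0.0145
  ... (17 more controls)
```

The instrumented ozone coefficient, −0.0222 (95% CI −0.0241 to
−0.0202), recovers the generator's truth of −0.0224 and reads as a
2.2% TFP loss per ppb of annual mean MDA8 ozone; the PM2.5 coefficient
reads as 0.89% per μg/m³. The Kleibergen–Paap F of 183 says the
wind-direction instruments are far from weak. Fitting the same panel
by `fit("ols")` instead gives an ozone coefficient biased toward zero
— the generator's endogeneity dial (`endogeneity_rho=0.5`) correlates
pollution shocks with the TFP error precisely to reproduce that
OLS/IV contrast.

Scenario projection — cap every county's annual ozone at the 31 ppb
WHO peak-season guideline and aggregate by output value:

```python
res = project(fit, panel, ScenarioSpec("ozone_annual", "cap_at_threshold", 31.0),
              year=2015)
print(res.summary())
```

```
national weighted TFP change: +12.06% (95% CI +10.80% to +13.33%)
```

i.e. in this synthetic panel, meeting the guideline in 2015 would have
raised national output-weighted TFP by about 12%, with the band from
the coefficient covariance via the delta method.

A command-line interface mirrors the stages
(`agriair simulate | metrics | tfp | fit | counterfactual | placebo | run`);
`agriair run --config cfg.yaml` executes the whole pipeline and writes
a manifest with per-stage checksums.

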