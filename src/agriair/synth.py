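"""Seeded synthetic county-year panels with known ground truth.

The generator is the inverse of the estimation problem: it lays down
counties on a map, gives each a wind regime tied to a spatial group,
builds daily weather and wind, drives pollution from wind-direction bin
counts through group-specific coefficients, injects a confounding shock
correlated with the outcome error (the endogeneity dial), and assembles
log TFP from the configured coefficients plus county and year fixed
effects.  Every downstream stage — exposure metrics, production-function
TFP, the wind-instrumented panel IV, counterfactuals and placebo tests —
can therefore be validated against known parameters without any external
data.

All randomness flows from one root seed through a single stream with a
fixed draw order, so identical (config, seed) produce byte-identical
panels; :func:`generate_daily_weather` exposes per-county-year slices of
the same realization.
"""

from __future__ import annotations

import dataclasses
import functools
import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import exposure, weather

__all__ = ["SynthConfig", "SyntheticTruth", "generate_daily_weather",
           "generate_panel", "weather_cube", "generate_production_records"]

logger = logging.getLogger(__name__)

_DAYS = 365
_MONTH_OF_DAY = np.repeat(np.arange(12), np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]))

#: Order of the continuous weather controls in the ``gamma`` vector
#: (five linear terms followed by their five squares).
GAMMA_ORDER = tuple(weather.CONTINUOUS_CONTROLS) + tuple(
    f"{c}_sq" for c in weather.CONTINUOUS_CONTROLS
)


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Configuration and ground-truth parameters of the generator.

    Coefficients are on the outcome scale of Eq.-style log TFP:
    ``beta_ozone`` is log TFP per ppb of annual mean MDA8 ozone,
    ``beta_pm`` per μg/m³ of PM2.5, ``beta_hot`` per day at or above
    35 °C.  ``endogeneity_rho`` is the correlation between the pollution
    shocks and the outcome error; ``wind_effect_scale`` scales the
    group-specific wind-bin coefficients (ppb per bin-day) that make the
    instruments relevant.
    """

    n_counties: int = 400
    n_years: int = 14
    n_groups_true: int = 8
    beta_ozone: float = -0.0224
    beta_pm: float = -0.0092
    beta_hot: float = -0.0050
    gamma: tuple[float, ...] = (2e-5, 5e-4, 1e-3, 0.0, 5e-3, 0.0, 0.0, 0.0, 0.0, 0.0)
    endogeneity_rho: float = 0.5
    fe_sd_county: float = 0.30
    fe_sd_year: float = 0.10
    noise_sd: float = 0.15
    wind_effect_scale: float = 0.12
    wind_concentration: float = 0.8
    ozone_shock_sd: float = 2.5
    pm_shock_sd: float = 8.0
    effect_basis: str = "annual"  # "annual" or "nonwinter" (zero winter effect)
    peak_ratio: float = 1.6
    first_year: int = 2002
    production_elasticities: tuple[float, ...] = (0.25, 0.30, 0.25, 0.20)
    seed: int = 0

    def __post_init__(self):
        if self.n_counties < 1 or self.n_years < 1 or self.n_groups_true < 1:
            raise ValueError("n_counties, n_years and n_groups_true must be positive")
        if self.n_groups_true > self.n_counties:
            raise ValueError("more wind-regime groups than counties")
        for name in ("fe_sd_county", "fe_sd_year", "noise_sd", "wind_effect_scale",
                     "ozone_shock_sd", "pm_shock_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1.0 <= self.endogeneity_rho <= 1.0:
            raise ValueError("endogeneity_rho must lie in [-1, 1]")
        if len(self.gamma) != len(GAMMA_ORDER):
            raise ValueError(f"gamma must have {len(GAMMA_ORDER)} entries ({GAMMA_ORDER})")
        if self.effect_basis not in ("annual", "nonwinter"):
            raise ValueError("effect_basis must be 'annual' or 'nonwinter'")
        n_slopes = 3 + len(self.gamma)  # pollution, heat and weather terms
        if self.n_counties * self.n_years < n_slopes + 1:
            raise ValueError("panel too small for the number of model parameters")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class SyntheticTruth:
    """Realized ground truth behind one synthetic panel."""

    alpha: pd.Series  # county fixed effects
    lam: pd.Series  # year fixed effects
    beta: pd.Series  # configured coefficient vector (pollution, heat, gamma)
    u: np.ndarray  # per-observation outcome error, county-major order
    groups: pd.Series  # true wind-regime group per county, 1..n_groups_true
    pi_ozone: np.ndarray  # (n_groups, 3) wind-bin coefficients, nonwinter
    pi_ozone_winter: np.ndarray
    pi_pm: np.ndarray


@functools.lru_cache(maxsize=2)
def weather_cube(config: SynthConfig) -> dict:
    """All daily weather/wind realizations for a config, keyed arrays of
    shape (n_counties, n_years, 365).  Cached; single fixed-order stream."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    C, Y, G = config.n_counties, config.n_years, config.n_groups_true

    # county geography and climate attributes
    lon = rng.uniform(78.0, 125.0, C)
    lat = rng.uniform(20.0, 46.0, C)
    base_temp = 29.0 - 0.55 * (lat - 20.0) + rng.normal(0, 1.0, C)
    seasonal_amp = 10.0 + rng.normal(0, 1.0, C)
    county_dir_offset = rng.normal(0.0, np.deg2rad(12.0), C)

    # spatial wind-regime groups from the coordinates
    km = KMeans(n_clusters=G, n_init=10, random_state=config.seed & 0x7FFFFFFF).fit(
        np.column_stack([lon, lat])
    )
    groups = km.labels_ + 1

    shape = (C, Y, _DAYS)
    tmean = (
        base_temp[:, None, None]
        + seasonal_amp[:, None, None] * np.cos(2 * np.pi * (np.arange(_DAYS) - 196) / _DAYS)
        + rng.normal(0, 3.0, shape)
    )
    half_range = np.maximum(rng.normal(4.5, 1.0, shape), 0.25)
    tmin = tmean - half_range
    tmax = tmean + half_range
    swap = tmin > tmax  # cannot occur by construction, kept as a guard
    tmin2 = np.where(swap, tmax, tmin)
    tmax = np.where(swap, tmin, tmax)
    tmin = tmin2

    precip = rng.exponential(2.5, shape)
    sunshine = np.clip(rng.normal(6.0, 2.0, shape), 0.0, 14.0)
    humidity = np.clip(rng.normal(65.0, 8.0, shape), 5.0, 100.0)
    pressure = rng.normal(1013.0, 4.0, shape)
    wind_speed = np.clip(rng.normal(3.0, 1.0, shape), 0.1, None)

    # wind direction: per-county von Mises whose mean depends on the true
    # group and drifts by (group, year) — the source of instrument relevance
    group_base = 2 * np.pi * (np.arange(G) / G)
    year_drift = rng.normal(0.0, np.deg2rad(40.0), (G, Y))
    mu = (
        group_base[groups - 1][:, None, None]
        + year_drift[groups - 1, :][:, :, None]
        + county_dir_offset[:, None, None]
    )
    wind_dir = np.degrees(rng.vonmises(mu, config.wind_concentration, shape)) % 360.0

    for name, arr in (("tmin", tmin), ("tmax", tmax), ("precip", precip),
                      ("wind_dir", wind_dir)):
        if not np.isfinite(arr).all():
            raise FloatingPointError(f"non-finite values generated for {name}")

    return {
        "lon": lon, "lat": lat, "groups": groups,
        "tmin": tmin, "tmax": tmax, "precip": precip, "sunshine": sunshine,
        "humidity": humidity, "pressure": pressure, "wind_speed": wind_speed,
        "wind_dir": wind_dir,
        # continue the stream deterministically for panel-level draws
        "_panel_rng_state": rng.bit_generator.state,
    }


def generate_daily_weather(config: SynthConfig, county: int, year: int) -> pd.DataFrame:
    """Daily weather series for one county-year of the realization.

    ``county`` is the 0-based county index; ``year`` is either a 0-based
    year index or a calendar year ≥ ``config.first_year``.  Returns a
    365-row frame with tmin ≤ tmax, wind direction in [0, 360) and all
    series finite; identical (config, county, year) always return the
    identical series.
    """
    if year >= config.first_year:
        year = year - config.first_year
    if not (0 <= county < config.n_counties) or not (0 <= year < config.n_years):
        raise ValueError("county or year outside the configured panel")
    cube = weather_cube(config)
    cols = {
        "tmin": cube["tmin"][county, year],
        "tmax": cube["tmax"][county, year],
        "precip": cube["precip"][county, year],
        "sunshine": cube["sunshine"][county, year],
        "humidity": cube["humidity"][county, year],
        "pressure": cube["pressure"][county, year],
        "wind_speed": cube["wind_speed"][county, year],
        "wind_direction": cube["wind_dir"][county, year],
    }
    return pd.DataFrame(cols)


def _annual_aggregates(config: SynthConfig, cube: dict) -> pd.DataFrame:
    """County-year weather controls and wind-bin counts from the cube."""
    C, Y = config.n_counties, config.n_years
    fracs = weather.temperature_bin_days(cube["tmin"], cube["tmax"])  # (C,Y,365,9)
    bin_days = fracs.sum(axis=2)  # (C, Y, 9)
    labels = weather.temperature_bin_labels()

    out = {}
    for i, lab in enumerate(labels):
        out[lab] = bin_days[..., i]
    out["precip"] = cube["precip"].sum(axis=2)
    out["sunshine"] = cube["sunshine"].sum(axis=2)
    out["humidity"] = cube["humidity"].mean(axis=2)
    out["pressure"] = cube["pressure"].mean(axis=2)
    out["wind_speed"] = cube["wind_speed"].mean(axis=2)
    for c in weather.CONTINUOUS_CONTROLS:
        out[f"{c}_sq"] = out[c] ** 2

    quadrant = np.floor_divide(cube["wind_dir"], 90.0).astype(int)
    for a in range(4):
        out[f"wd_bin_{a}"] = (quadrant == a).sum(axis=2).astype(float)

    flat = {k: v.reshape(C * Y) for k, v in out.items()}
    county_idx = np.repeat(np.arange(C), Y)
    year_idx = np.tile(np.arange(Y), C)
    df = pd.DataFrame(flat)
    df.insert(0, "county", county_idx)
    df.insert(1, "year", config.first_year + year_idx)
    return df


def generate_panel(config: SynthConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one county-year panel and its ground truth.

    The outcome satisfies, exactly,

        log TFP = β_O3·O3 + β_PM·PM + β_hot·(days ≥ 35 °C) + X'γ
                  + α_i + λ_t + u_it

    with O3 and PM built from group-specific wind-bin responses plus a
    confounding shock whose correlation with u_it is ``endogeneity_rho``.
    """
    cube = weather_cube(config)
    C, Y, G = config.n_counties, config.n_years, config.n_groups_true
    panel = _annual_aggregates(config, cube)
    groups = np.asarray(cube["groups"], dtype=np.int64)
    panel["group"] = groups[panel["county"].to_numpy()]
    panel["lon"] = cube["lon"][panel["county"].to_numpy()]
    panel["lat"] = cube["lat"][panel["county"].to_numpy()]

    rng = np.random.default_rng()
    rng.bit_generator.state = cube["_panel_rng_state"]

    # fixed effects, outcome error, pollution shocks
    alpha = rng.normal(0.0, config.fe_sd_county, C)
    lam = rng.normal(0.0, config.fe_sd_year, Y)
    u = rng.normal(0.0, config.noise_sd, (C, Y)) if config.noise_sd > 0 else np.zeros((C, Y))

    def correlated_shock(sd: float) -> np.ndarray:
        z = rng.normal(0.0, 1.0, (C, Y))
        rho = config.endogeneity_rho
        if sd == 0:
            return np.zeros((C, Y))
        if rho == 0 or config.noise_sd == 0:
            return sd * z
        return rho * (sd / config.noise_sd) * u + np.sqrt(1 - rho**2) * sd * z

    shock_o = correlated_shock(config.ozone_shock_sd)
    shock_pm = correlated_shock(config.pm_shock_sd)

    # group-specific wind-bin responses (ppb per bin-day)
    pi_nw = config.wind_effect_scale * rng.normal(0.0, 1.0, (G, 3))
    pi_w = config.wind_effect_scale * rng.normal(0.0, 1.0, (G, 3))
    pi_pm = 1.5 * config.wind_effect_scale * rng.normal(0.0, 1.0, (G, 3))
    month_noise = rng.normal(0.0, 1.0, (C, Y, 12))

    wd = panel[[f"wd_bin_{a}" for a in range(3)]].to_numpy().reshape(C, Y, 3)
    g_idx = groups - 1
    wind_comp_nw = np.einsum("cya,ca->cy", wd, pi_nw[g_idx])
    wind_comp_w = np.einsum("cya,ca->cy", wd, pi_w[g_idx])
    wind_comp_pm = np.einsum("cya,ca->cy", wd, pi_pm[g_idx])

    sun_mean = cube["sunshine"].mean(axis=2)
    ws_mean = cube["wind_speed"].mean(axis=2)
    hum_mean = cube["humidity"].mean(axis=2)

    months = np.arange(1, 13)
    seasonal = 38.0 + 12.0 * np.cos(2 * np.pi * (months - 7) / 12.0)
    winter_mask = np.isin(months, exposure.WINTER_MONTHS)
    wind_comp_monthly = np.where(
        winter_mask[None, None, :], wind_comp_w[:, :, None], wind_comp_nw[:, :, None]
    )
    ozone_weather = 0.5 * (sun_mean - 6.0) - 0.3 * (ws_mean - 3.0)
    ozone_monthly = (
        seasonal[None, None, :]
        + wind_comp_monthly
        + (ozone_weather + shock_o)[:, :, None]
        + month_noise
    )
    ozone_monthly = np.clip(ozone_monthly, 0.5, None)

    pm = 55.0 + wind_comp_pm - 2.0 * (ws_mean - 3.0) - 0.1 * (hum_mean - 65.0) + shock_pm
    pm = np.clip(pm, 1.0, None)

    for name, arr in (("ozone_monthly", ozone_monthly), ("pm25", pm)):
        if not np.isfinite(arr).all():
            raise FloatingPointError(f"non-finite values generated for {name}")

    ozone_annual = ozone_monthly.mean(axis=2)
    ozone_winter = ozone_monthly[:, :, winter_mask].mean(axis=2)
    ozone_nonwinter = ozone_monthly[:, :, ~winter_mask].mean(axis=2)
    indices = exposure.annual_indices_from_monthly(ozone_monthly, config.peak_ratio)

    panel["ozone_annual"] = ozone_annual.reshape(-1)
    panel["ozone_winter"] = ozone_winter.reshape(-1)
    panel["ozone_nonwinter"] = ozone_nonwinter.reshape(-1)
    panel["pm25"] = pm.reshape(-1)
    for k, v in indices.items():
        panel[k] = v.reshape(-1)

    # outcome
    gamma = pd.Series(config.gamma, index=list(GAMMA_ORDER))
    xg = panel[list(GAMMA_ORDER)].to_numpy() @ gamma.to_numpy()
    hot = panel["tbin_ge35"].to_numpy()
    o3_basis = (
        ozone_annual if config.effect_basis == "annual" else ozone_nonwinter
    ).reshape(-1)
    ci = panel["county"].to_numpy()
    yi = (panel["year"] - config.first_year).to_numpy()
    log_tfp = (
        config.beta_ozone * o3_basis
        + config.beta_pm * panel["pm25"].to_numpy()
        + config.beta_hot * hot
        + xg
        + alpha[ci]
        + lam[yi]
        + u.reshape(-1)
    )
    panel["log_tfp"] = log_tfp
    panel["tfp"] = np.exp(log_tfp)

    weights = rng.lognormal(0.0, 0.6, C)
    panel["weight"] = weights[ci]

    beta = pd.Series(
        {
            "ozone_annual" if config.effect_basis == "annual" else "ozone_nonwinter":
                config.beta_ozone,
            "pm25": config.beta_pm,
            "tbin_ge35": config.beta_hot,
            **gamma.to_dict(),
        }
    )
    truth = SyntheticTruth(
        alpha=pd.Series(alpha, name="alpha"),
        lam=pd.Series(lam, index=config.first_year + np.arange(Y), name="lambda"),
        beta=beta,
        u=u.reshape(-1),
        groups=pd.Series(groups, name="group"),
        pi_ozone=pi_nw,
        pi_ozone_winter=pi_w,
        pi_pm=pi_pm,
    )
    return panel, truth


def generate_production_records(
    config: SynthConfig, panel: pd.DataFrame
) -> pd.DataFrame:
    """Production records whose Cobb–Douglas residual equals the panel's
    log TFP up to the configured elasticities (for exercising the
    production-function estimators end to end)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA9)))
    C = config.n_counties
    ci = panel["county"].to_numpy()
    yi = (panel["year"] - config.first_year).to_numpy()
    base = rng.normal(8.0, 0.5, (C, 4))
    trend = rng.normal(0.0, 0.02, (C, 4))
    noise = rng.normal(0.0, 0.05, (len(panel), 4))
    ln_inputs = base[ci] + trend[ci] * yi[:, None] + noise
    elast = np.asarray(config.production_elasticities)
    ln_y = ln_inputs @ elast + panel["log_tfp"].to_numpy()
    rec = pd.DataFrame(
        {
            "county": panel["county"],
            "year": panel["year"],
            "output": np.exp(ln_y),
        }
    )
    from .production import INPUTS

    for j, name in enumerate(INPUTS):
        rec[name] = np.exp(ln_inputs[:, j])
    return rec
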