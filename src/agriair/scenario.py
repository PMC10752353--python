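"""Counterfactual exposure scenarios and projected TFP changes.

Given a fitted panel model, predicts county-level percent TFP changes
between the observed exposure path and a hypothetical one — exposures
held at a reference year, capped at a guideline threshold (e.g. the WHO
peak-season ozone guideline of 31 ppb, or PM2.5 at 35 μg/m³), or daily
temperatures uniformly shifted (e.g. +2 °C warming) — and aggregates
them to a national change weighted by county output value, with a
delta-method 95% confidence band propagating the coefficient
cluster-robust covariance.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import weather
from .paneliv import PanelIVResults

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "apply_scenario",
    "predict_tfp_change",
    "aggregate_weighted",
    "project",
]

logger = logging.getLogger(__name__)

_RULES = ("fix_to_reference_year", "cap_at_threshold", "uniform_shift")
_VARIABLES = ("ozone_annual", "ozone_nonwinter", "ozone_winter", "pm25", "temperature")


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One perturbation rule applied to one driver.

    ``variable`` is an exposure column (or ``"temperature"``, which
    shifts daily temperatures and recomputes every temperature bin);
    ``rule`` is one of ``fix_to_reference_year`` (value = reference
    year), ``cap_at_threshold`` (value = threshold) or ``uniform_shift``
    (value = shift, °C; temperature only).
    """

    variable: str
    rule: str
    value: float

    def __post_init__(self):
        if self.variable not in _VARIABLES:
            raise ValueError(f"unknown scenario variable {self.variable!r}")
        if self.rule not in _RULES:
            raise ValueError(f"unknown scenario rule {self.rule!r}")
        if not np.isfinite(self.value):
            raise ValueError("scenario value must be finite")
        if self.rule == "uniform_shift" and self.variable != "temperature":
            raise ValueError("uniform_shift applies to temperature only")
        if self.variable == "temperature" and self.rule == "cap_at_threshold":
            raise ValueError("temperature supports fix_to_reference_year or uniform_shift")


def apply_scenario(
    panel: pd.DataFrame,
    spec: ScenarioSpec,
    daily: dict | None = None,
) -> pd.DataFrame:
    """Return the panel under the hypothetical exposure path.

    For temperature scenarios, ``daily`` must supply the daily ``tmin``
    and ``tmax`` arrays of shape (n_counties, n_years, 365) aligned with
    the panel's county-major row order (e.g. the generator's weather
    cube); every temperature bin is recomputed from the shifted days.
    """
    out = panel.copy()
    if spec.variable == "temperature":
        if daily is None:
            raise ValueError("temperature scenarios need the daily weather arrays")
        shift = spec.value if spec.rule == "uniform_shift" else 0.0
        tmin = daily["tmin"] + shift
        tmax = daily["tmax"] + shift
        if spec.rule == "fix_to_reference_year":
            return _fix_to_reference(out, _temperature_columns(out), int(spec.value))
        fracs = weather.temperature_bin_days(tmin, tmax).sum(axis=2)
        labels = weather.temperature_bin_labels()
        flat = fracs.reshape(-1, len(labels))
        if len(flat) != len(out):
            raise ValueError("daily arrays do not align with the panel rows")
        for i, lab in enumerate(labels):
            out[lab] = flat[:, i]
        return out

    if spec.variable not in out.columns:
        raise KeyError(f"panel lacks scenario variable {spec.variable!r}")
    if spec.rule == "cap_at_threshold":
        out[spec.variable] = np.minimum(out[spec.variable], spec.value)
    elif spec.rule == "fix_to_reference_year":
        out = _fix_to_reference(out, [spec.variable], int(spec.value))
    else:  # pragma: no cover - blocked by ScenarioSpec validation
        raise ValueError(spec.rule)
    return out


def _temperature_columns(panel: pd.DataFrame) -> list[str]:
    return [c for c in weather.temperature_bin_labels() if c in panel.columns]


def _fix_to_reference(panel: pd.DataFrame, columns: list[str], ref_year: int) -> pd.DataFrame:
    ref = panel.loc[panel["year"] == ref_year, ["county", *columns]]
    missing = set(panel["county"]) - set(ref["county"])
    if ref.empty or missing:
        raise ValueError(
            f"reference year {ref_year} missing for counties: {sorted(missing)[:10]}"
        )
    out = panel.drop(columns=columns).merge(ref, on="county", how="left")
    out.index = panel.index
    return out


def predict_tfp_change(
    fit: PanelIVResults,
    observed: pd.DataFrame,
    perturbed: pd.DataFrame,
) -> pd.DataFrame:
    """County-year percent TFP changes between two exposure paths.

    Exact for the log-linear model: 100·(exp(β'Δx) − 1), using only the
    columns that differ; the first-order reading 100·β'Δx (the
    coefficient-×100 semi-elasticity) is emitted alongside.
    """
    covs = list(fit.params.index)
    missing = [c for c in covs if c not in perturbed.columns]
    if missing:
        raise KeyError(f"perturbed panel lacks model covariates: {missing}")
    if len(observed) != len(perturbed):
        raise ValueError("observed and perturbed panels must align row-wise")
    delta = perturbed[covs].to_numpy(float) - observed[covs].to_numpy(float)
    eta = delta @ fit.params.to_numpy()
    out = observed[["county", "year"]].copy()
    out["pct_change"] = 100.0 * (np.exp(eta) - 1.0)
    out["pct_change_linear"] = 100.0 * eta
    out["_eta"] = eta
    out["_delta_idx"] = list(range(len(out)))
    out.attrs["delta"] = delta
    return out


def aggregate_weighted(
    changes: pd.DataFrame,
    weights: np.ndarray | pd.Series,
    fit: PanelIVResults | None = None,
    alpha: float = 0.05,
) -> "ScenarioResult":
    """Output-value-weighted national percent change with a confidence band.

    The band is the delta method holding Δx fixed: the gradient of the
    weighted mean of 100·(exp(δ'β)−1) with respect to β, propagated
    through the coefficient cluster-robust covariance.  Requires the
    ``changes`` frame produced by :func:`predict_tfp_change` when a CI
    is requested.
    """
    w = np.asarray(weights, float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must not be all zero")
    w = w / w.sum()
    pct = changes["pct_change"].to_numpy()
    national = float(w @ pct)

    ci = (float("nan"), float("nan"))
    if fit is not None and "delta" in changes.attrs:
        delta = changes.attrs["delta"]
        eta = changes["_eta"].to_numpy()
        grad = 100.0 * (delta * np.exp(eta)[:, None]).T @ w
        var = float(grad @ fit.cov.to_numpy() @ grad)
        from scipy import stats

        q = stats.norm.ppf(1 - alpha / 2)
        half = q * np.sqrt(max(var, 0.0))
        ci = (national - half, national + half)

    return ScenarioResult(
        county_changes=changes[["county", "year", "pct_change", "pct_change_linear"]],
        national_pct_change=national,
        conf_int=ci,
        weights=pd.Series(w, index=changes.index, name="weight"),
    )


@dataclasses.dataclass
class ScenarioResult:
    """County-level and weighted national percent TFP changes."""

    county_changes: pd.DataFrame
    national_pct_change: float
    conf_int: tuple[float, float]
    weights: pd.Series

    def summary(self) -> str:
        lo, hi = self.conf_int
        return (
            f"national weighted TFP change: {self.national_pct_change:+.2f}% "
            f"(95% CI {lo:+.2f}% to {hi:+.2f}%)"
        )


def project(
    fit: PanelIVResults,
    panel: pd.DataFrame,
    spec: ScenarioSpec,
    weights_col: str = "weight",
    daily: dict | None = None,
    year: int | None = None,
) -> ScenarioResult:
    """Apply a scenario, predict changes and aggregate, in one call.

    ``year`` restricts the aggregation to a single panel year (the
    national bar for that year); by default all county-years enter.
    """
    if year is not None and year not in set(panel["year"]):
        raise ValueError(f"year {year} not in panel (years {sorted(set(panel['year']))[:3]}..)")
    perturbed = apply_scenario(panel, spec, daily=daily)
    changes = predict_tfp_change(fit, panel, perturbed)
    keep = slice(None) if year is None else (panel["year"] == year).to_numpy()
    changes_kept = changes.loc[keep] if year is not None else changes
    if year is not None:
        changes_kept = changes_kept.copy()
        changes_kept.attrs["delta"] = changes.attrs["delta"][keep]
    weights = panel.loc[keep, weights_col] if year is not None else panel[weights_col]
    return aggregate_weighted(changes_kept, weights, fit=fit)
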