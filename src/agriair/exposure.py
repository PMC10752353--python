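"""Ozone exposure metrics.

Maximum daily 8-hour average (MDA8) ozone, molar unit conversion, the
peak/nonpeak hourly reconstruction used to recover hourly series from
monthly MDA8 means, and the three cumulative vegetation-exposure indices
(AOT40, SUM06, W126).

Units are tracked explicitly.  AOT40 and SUM06 are defined on the ppb
scale; W126 uses the EPA sigmoid weighting whose constants (4403, 126)
are on the ppm scale, so ppb inputs are converted internally.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

__all__ = [
    "HourlySeries",
    "mda8",
    "ugm3_to_ppb",
    "ppb_to_ugm3",
    "estimate_ratios",
    "reconstruct_hourly",
    "aot40",
    "sum06",
    "w126",
    "w126_weight",
    "seasonal_means",
    "annual_indices_from_monthly",
    "PEAK_HOURS",
    "WINTER_MONTHS",
]

logger = logging.getLogger(__name__)

#: Gas constant, J mol^-1 K^-1.
_R = 8.314462618

#: Molar mass of ozone, g/mol.
MOLAR_MASS_O3 = 48.00

#: Hours of the day treated as the "peak 8 h" window when reconstructing
#: hourly series from monthly MDA8 means (daytime photochemical peak).
PEAK_HOURS = tuple(range(10, 18))

#: Calendar months treated as winter.
WINTER_MONTHS = (12, 1, 2)

#: Minimum valid hours for a day to yield an MDA8 value, and minimum
#: valid hours within an 8-h window for the window mean to count.
MIN_VALID_HOURS_DAY = 18
MIN_VALID_HOURS_WINDOW = 6

_DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


class UnitError(ValueError):
    """Raised when a series carries the wrong concentration unit."""


@dataclasses.dataclass
class HourlySeries:
    """An hourly concentration series with an explicit unit tag.

    Parameters
    ----------
    values : array-like
        Hourly concentrations; NaN marks missing hours.
    unit : str
        One of ``"ppb"``, ``"ppm"`` or ``"ug/m3"``.
    timestamps : pandas.DatetimeIndex, optional
        Hour-resolution timestamps aligned with ``values``.
    """

    values: np.ndarray
    unit: str = "ppb"
    timestamps: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in ("ppb", "ppm", "ug/m3"):
            raise UnitError(f"unknown concentration unit {self.unit!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("negative concentrations; flag missing hours as NaN")
        if self.timestamps is not None and len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def to_unit(self, unit: str) -> "HourlySeries":
        """Return the series converted between ppb and ppm.

        Mass-per-volume units require temperature/pressure context; use
        :func:`ugm3_to_ppb` for those.
        """
        if unit == self.unit:
            return self
        if {self.unit, unit} == {"ppb", "ppm"}:
            factor = 1e-3 if unit == "ppm" else 1e3
            return HourlySeries(self.values * factor, unit, self.timestamps)
        raise UnitError(
            f"cannot convert {self.unit!r} to {unit!r} without temperature/pressure"
        )


def _require_unit(series: HourlySeries, unit: str) -> np.ndarray:
    if series.unit != unit:
        raise UnitError(f"expected {unit!r} series, got {series.unit!r}")
    return series.values


def mda8(day: HourlySeries | np.ndarray) -> float:
    """Maximum daily 8-hour average concentration for one 24-h day.

    The maximum is taken over the 17 complete same-day 8-hour windows
    (start hours 0..16).  A day with fewer than 18 valid hours, or no
    window with at least 6 valid hours, returns NaN rather than raising.
    """
    values = day.values if isinstance(day, HourlySeries) else np.asarray(day, float)
    if isinstance(day, HourlySeries):
        _require_unit(day, "ppb")
    if values.shape != (24,):
        raise ValueError(f"expected 24 hourly values, got shape {values.shape}")
    valid = np.isfinite(values)
    if valid.sum() < MIN_VALID_HOURS_DAY:
        return float("nan")
    best = np.nan
    for start in range(17):
        window = values[start : start + 8]
        wvalid = np.isfinite(window)
        if wvalid.sum() < MIN_VALID_HOURS_WINDOW:
            continue
        mean = np.nanmean(window)
        if np.isnan(best) or mean > best:
            best = mean
    return float(best)


def ugm3_to_ppb(
    conc: float | np.ndarray,
    temperature_k: float = 298.0,
    pressure_hpa: float = 1013.0,
    molar_mass: float = MOLAR_MASS_O3,
) -> float | np.ndarray:
    """Convert a mass concentration (μg/m³) to a mixing ratio (ppb).

    Uses the ideal-gas molar volume R·T/P: ppb = μg/m³ × (R·T/P) / M with
    T in kelvin, P in hPa and M in g/mol.  At 298 K and 1013 hPa, 60 μg/m³
    of ozone is 30.6 ppb (31 ppb after rounding).
    """
    if np.any(np.asarray(temperature_k) <= 0) or np.any(np.asarray(pressure_hpa) <= 0):
        raise ValueError("temperature and pressure must be positive")
    molar_volume_l = _R * temperature_k / (pressure_hpa * 100.0) * 1e3  # L/mol
    return conc * molar_volume_l / molar_mass


def ppb_to_ugm3(
    conc: float | np.ndarray,
    temperature_k: float = 298.0,
    pressure_hpa: float = 1013.0,
    molar_mass: float = MOLAR_MASS_O3,
) -> float | np.ndarray:
    """Inverse of :func:`ugm3_to_ppb`."""
    if np.any(np.asarray(temperature_k) <= 0) or np.any(np.asarray(pressure_hpa) <= 0):
        raise ValueError("temperature and pressure must be positive")
    molar_volume_l = _R * temperature_k / (pressure_hpa * 100.0) * 1e3
    return conc * molar_mass / molar_volume_l


def _day_peak_nonpeak(values: np.ndarray) -> tuple[float, float]:
    """Mean over the best 8-h window and over the remaining 16 hours."""
    best_mean, best_start = -np.inf, 0
    for start in range(17):
        mean = values[start : start + 8].mean()
        if mean > best_mean:
            best_mean, best_start = mean, start
    mask = np.ones(24, bool)
    mask[best_start : best_start + 8] = False
    return float(best_mean), float(values[mask].mean())


def estimate_ratios(
    observed: pd.DataFrame,
    region_col: str = "region",
) -> pd.DataFrame:
    """Estimate peak/nonpeak concentration ratios by region and month.

    Parameters
    ----------
    observed : DataFrame
        Hourly observations with columns ``region``, ``timestamp``
        (hour resolution) and ``concentration`` (ppb).  Only complete
        24-hour days contribute.

    Returns
    -------
    DataFrame with columns ``region``, ``month``, ``ratio`` where ratio is
    (mean over days of the peak-8h mean) / (mean over days of the
    nonpeak-16h mean).
    """
    df = observed.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    df["month"] = df["timestamp"].dt.month
    rows = []
    for (region, month), cell in df.groupby([region_col, "month"]):
        peaks, nonpeaks = [], []
        for _, day in cell.groupby("date"):
            if len(day) != 24 or day["concentration"].isna().any():
                continue
            vals = day.sort_values("timestamp")["concentration"].to_numpy(float)
            p, np_ = _day_peak_nonpeak(vals)
            peaks.append(p)
            nonpeaks.append(np_)
        if not peaks:
            logger.warning("no complete day for region=%s month=%s", region, month)
            continue
        denom = float(np.mean(nonpeaks))
        if denom <= 0:
            logger.warning("nonpositive nonpeak mean for region=%s month=%s", region, month)
            continue
        rows.append({region_col: region, "month": month, "ratio": float(np.mean(peaks)) / denom})
    return pd.DataFrame(rows, columns=[region_col, "month", "ratio"])


def reconstruct_hourly(
    monthly: pd.DataFrame,
    ratios: pd.DataFrame,
    region_col: str = "region",
) -> dict[tuple, HourlySeries]:
    """Reconstruct hourly series from monthly MDA8 means and peak ratios.

    Every day of a month gets the same profile: the 8 peak hours equal the
    monthly mean MDA8 and the 16 nonpeak hours equal MDA8 / ratio.

    Parameters
    ----------
    monthly : DataFrame
        Columns ``region``, ``year``, ``month``, ``mda8`` (ppb).
    ratios : DataFrame
        Columns ``region``, ``month``, ``ratio``.

    Returns
    -------
    dict mapping (region, year, month) to an :class:`HourlySeries` of
    length ``days_in_month * 24``.
    """
    ratio_map = {(r[region_col], r["month"]): r["ratio"] for _, r in ratios.iterrows()}
    missing = sorted(
        {(r[region_col], r["month"]) for _, r in monthly.iterrows()} - set(ratio_map)
    )
    if missing:
        raise KeyError(f"missing peak/nonpeak ratios for keys: {missing}")
    out: dict[tuple, HourlySeries] = {}
    for _, row in monthly.iterrows():
        month = int(row["month"])
        ratio = ratio_map[(row[region_col], month)]
        peak = float(row["mda8"])
        nonpeak = peak / ratio
        day = np.full(24, nonpeak)
        day[list(PEAK_HOURS)] = peak
        n_days = int(_DAYS_PER_MONTH[month - 1])
        out[(row[region_col], int(row["year"]), month)] = HourlySeries(
            np.tile(day, n_days), "ppb"
        )
    return out


def aot40(series: HourlySeries) -> float:
    """AOT40: sum of (C_h − 40) over hours with C_h strictly above 40 ppb."""
    values = _require_unit(series, "ppb")
    excess = values - 40.0
    return float(np.nansum(np.where(values > 40.0, excess, 0.0)))


def sum06(series: HourlySeries) -> float:
    """SUM06: sum of C_h over hours with C_h strictly above 60 ppb."""
    values = _require_unit(series, "ppb")
    return float(np.nansum(np.where(values > 60.0, values, 0.0)))


def w126_weight(c_ppm: float | np.ndarray) -> float | np.ndarray:
    """The W126 sigmoid weight 1 / (1 + 4403·exp(−126·C)) with C in ppm.

    Strictly increasing in concentration and bounded in (0, 1).
    """
    return 1.0 / (1.0 + 4403.0 * np.exp(-126.0 * np.asarray(c_ppm, float)))


def w126(series: HourlySeries) -> float:
    """W126: sigmoid-weighted sum of hourly concentrations, in ppm·hours.

    The constants (4403, 126) are on the ppm scale (EPA convention); ppb
    input is converted internally.
    """
    if series.unit == "ug/m3":
        raise UnitError("convert mass concentrations to ppb or ppm first")
    c_ppm = series.to_unit("ppm").values
    return float(np.nansum(c_ppm * w126_weight(c_ppm)))


def seasonal_means(
    monthly: pd.DataFrame,
    region_col: str = "region",
    winter_months: tuple[int, ...] = WINTER_MONTHS,
) -> pd.DataFrame:
    """Winter and nonwinter means of monthly MDA8 values per region-year.

    Winter defaults to calendar months 12, 1 and 2 of the same panel year.
    Returns columns ``region``, ``year``, ``winter``, ``nonwinter``; a
    season with no months present yields NaN (logged).
    """
    rows = []
    for (region, year), cell in monthly.groupby([region_col, "year"]):
        in_winter = cell["month"].isin(winter_months)
        winter = cell.loc[in_winter, "mda8"].mean()
        nonwinter = cell.loc[~in_winter, "mda8"].mean()
        for label, value in (("winter", winter), ("nonwinter", nonwinter)):
            if np.isnan(value):
                logger.warning("all-missing %s season for region=%s year=%s", label, region, year)
        rows.append(
            {region_col: region, "year": int(year), "winter": winter, "nonwinter": nonwinter}
        )
    return pd.DataFrame(rows)


def annual_indices_from_monthly(
    mda8_by_month: np.ndarray,
    ratio: float | np.ndarray = 1.6,
    days_per_month: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Annual AOT40/SUM06/W126 from 12 monthly MDA8 means, in closed form.

    Under the reconstruction rule (8 peak hours at the monthly MDA8, 16
    nonpeak hours at MDA8/ratio, identical days within a month) each
    index is a weighted sum over months of two hourly levels, so the full
    hourly expansion is unnecessary.  ``mda8_by_month`` may carry leading
    dimensions (e.g. counties × years × 12); the indices are returned with
    those leading dimensions.

    Agrees exactly with building the hourly series via
    :func:`reconstruct_hourly` and applying :func:`aot40` etc.
    """
    m = np.asarray(mda8_by_month, float)
    if m.shape[-1] != 12:
        raise ValueError("last axis must hold 12 monthly values")
    if days_per_month is None:
        days_per_month = _DAYS_PER_MONTH
    ratio = np.asarray(ratio, float)
    peak = m
    nonpeak = m / ratio
    h_peak = 8.0 * days_per_month
    h_nonpeak = 16.0 * days_per_month

    def _sum(level_fn):
        return (h_peak * level_fn(peak) + h_nonpeak * level_fn(nonpeak)).sum(axis=-1)

    out = {
        "aot40": _sum(lambda c: np.where(c > 40.0, c - 40.0, 0.0)),
        "sum06": _sum(lambda c: np.where(c > 60.0, c, 0.0)),
        "w126": _sum(lambda c: (c / 1e3) * w126_weight(c / 1e3)),
    }
    return out
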