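"""Station weather to regression controls.

The regression's weather control set: fractional day counts per 5 °C
temperature bin from a single-sine interpolation of daily min/max,
annual aggregates with quadratic terms, wind-direction bin counts,
inverse-distance-weighted (IDW) interpolation to county centroids, and
k-means spatial grouping of counties.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "DEFAULT_BIN_EDGES",
    "temperature_bin_labels",
    "temperature_bin_days",
    "annual_weather_controls",
    "wind_direction_bins",
    "idw_interpolate",
    "kmeans_groups",
    "GroupAssignment",
    "WIND_BIN_COLUMNS",
    "CONTINUOUS_CONTROLS",
]

logger = logging.getLogger(__name__)

#: Interior edges of the 5 °C bins: first bin (−inf, 0), last [35, inf).
DEFAULT_BIN_EDGES = tuple(float(e) for e in range(0, 40, 5))

#: Continuous weather controls entering the regression with linear and
#: quadratic terms.
CONTINUOUS_CONTROLS = ("precip", "sunshine", "humidity", "pressure", "wind_speed")

WIND_BIN_COLUMNS = ("wd_bin_0", "wd_bin_1", "wd_bin_2", "wd_bin_3")

_EARTH_RADIUS_KM = 6371.0088


def temperature_bin_labels(bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES) -> list[str]:
    """Column labels for the bins implied by ``bin_edges``."""
    labels = [f"tbin_lt{bin_edges[0]:g}"]
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        labels.append(f"tbin_{lo:g}_{hi:g}")
    labels.append(f"tbin_ge{bin_edges[-1]:g}")
    return labels


def _fraction_below(thresholds, mean, amplitude):
    """Fraction of the day the sinusoid mean + amplitude·sin(2πt) spends
    below each threshold; closed form via the arcsine distribution.

    ``thresholds`` is a 1-D array of edges; the result appends a trailing
    axis of the same length to the broadcast shape of mean/amplitude.
    A constant day (amplitude 0) degenerates to the step indicator.
    """
    edges = np.asarray(thresholds, float)
    mean = np.asarray(mean, float)[..., None]
    amp = np.asarray(amplitude, float)[..., None]
    degenerate = amp <= 0
    s = (edges - mean) / np.where(degenerate, 1.0, amp)
    # clipping makes arcsin exact at the endpoints (fraction 0 below tmin,
    # 1 above tmax), so no separate boundary branch is needed
    np.clip(s, -1.0, 1.0, out=s)
    np.arcsin(s, out=s)
    s /= np.pi
    s += 0.5
    if degenerate.any():
        indicator = np.broadcast_to((edges > mean) * 1.0, s.shape)
        s = np.where(degenerate, indicator, s)
    return s


def temperature_bin_days(
    tmin,
    tmax,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
):
    """Fractional day spent in each temperature bin, by the single-sine method.

    The within-day temperature path is T(t) = m + A·sin(2πt) with
    m = (tmin+tmax)/2 and A = (tmax−tmin)/2, attaining tmin and tmax once
    each; the time below a threshold has the closed arcsine form.  Bins
    are half-open [a, b) with open first bin (−inf, edges[0]) and last
    bin [edges[-1], ∞).

    Parameters
    ----------
    tmin, tmax : float or ndarray
        Daily minimum and maximum temperature (°C); broadcastable.

    Returns
    -------
    ndarray with a trailing axis of length ``len(bin_edges) + 1``;
    fractions are nonnegative and sum to 1 over that axis.
    """
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    if np.any(tmin > tmax):
        raise ValueError("tmin must not exceed tmax")
    mean = (tmin + tmax) / 2.0
    amp = (tmax - tmin) / 2.0
    # cumulative fraction below each interior edge, then difference
    below = _fraction_below(np.asarray(bin_edges, float), mean, amp)
    first = below[..., :1]
    interior = np.diff(below, axis=-1)
    last = 1.0 - below[..., -1:]
    return np.concatenate([first, interior, last], axis=-1)


def annual_weather_controls(
    daily: pd.DataFrame,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.Series:
    """Aggregate one county-year of daily weather into the control set.

    Parameters
    ----------
    daily : DataFrame
        One row per day with columns ``tmin``, ``tmax``, ``precip``,
        ``sunshine``, ``humidity``, ``pressure``, ``wind_speed``.

    Returns
    -------
    Series with fractional day counts per temperature bin, cumulative
    precipitation, total sunshine hours, means of humidity/pressure/wind
    speed, squared terms of the five continuous controls, and a
    ``coverage`` field (fraction of days with complete records).
    """
    needed = ["tmin", "tmax", *CONTINUOUS_CONTROLS]
    complete = daily[needed].notna().all(axis=1)
    coverage = float(complete.mean()) if len(daily) else 0.0
    if coverage < 0.9:
        logger.warning("county-year has only %.0f%% complete days", 100 * coverage)
    rows = daily.loc[complete]
    fracs = temperature_bin_days(
        rows["tmin"].to_numpy(), rows["tmax"].to_numpy(), bin_edges
    ).sum(axis=0)
    out = dict(zip(temperature_bin_labels(bin_edges), fracs))
    out["precip"] = float(rows["precip"].sum())
    out["sunshine"] = float(rows["sunshine"].sum())
    out["humidity"] = float(rows["humidity"].mean())
    out["pressure"] = float(rows["pressure"].mean())
    out["wind_speed"] = float(rows["wind_speed"].mean())
    for name in CONTINUOUS_CONTROLS:
        out[f"{name}_sq"] = out[name] ** 2
    out["coverage"] = coverage
    return pd.Series(out)


def wind_direction_bins(directions) -> np.ndarray:
    """Count days whose mean wind direction falls in each 90° quadrant.

    Quadrants are the half-open intervals [0,90), [90,180), [180,270),
    [270,360).  Directions outside [0, 360) are normalized modulo 360
    with a warning.  Counts sum to the number of days.
    """
    d = np.asarray(directions, float)
    if np.any((d < 0) | (d >= 360)):
        logger.warning("wind directions outside [0, 360) normalized modulo 360")
        d = np.mod(d, 360.0)
    idx = np.floor_divide(d, 90.0).astype(int)
    return np.bincount(idx, minlength=4).astype(float)


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between (lon, lat) points, in km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def idw_interpolate(
    stations: pd.DataFrame,
    target: tuple[float, float],
    radius_km: float = 200.0,
    power: float = 1.0,
    value_col: str = "value",
) -> float:
    """Inverse-distance-weighted mean of station values at a target point.

    Stations beyond ``radius_km`` (great-circle) are ignored; weights are
    distance^(−power).  A station exactly at the target short-circuits to
    its own value.  No station in radius yields NaN (logged).

    Parameters
    ----------
    stations : DataFrame
        Columns ``lon``, ``lat`` and ``value_col``.
    target : (lon, lat)
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    d = haversine_km(
        stations["lon"].to_numpy(), stations["lat"].to_numpy(), target[0], target[1]
    )
    values = stations[value_col].to_numpy(float)
    keep = (d <= radius_km) & np.isfinite(values)
    if not keep.any():
        logger.warning("no station within %.0f km of %s", radius_km, target)
        return float("nan")
    d, values = d[keep], values[keep]
    at_target = d < 1e-9
    if at_target.any():
        return float(values[at_target][0])
    w = d**-power
    return float(np.average(values, weights=w))


@dataclasses.dataclass
class GroupAssignment:
    """County-to-group labels (1..k) and group centroids in (lon, lat)."""

    labels: pd.Series  # index: county id, values in 1..k
    centroids: np.ndarray  # shape (k, 2)
    inertia: float  # within-cluster sum of squares

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def kmeans_groups(
    coords: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> GroupAssignment:
    """Group counties by k-means on their coordinates.

    Lloyd's algorithm with k-means++ initialization, best of ``n_init``
    restarts at a fixed seed.  Mirrors the spatial grouping used to let
    wind-direction responses vary regionally.

    Parameters
    ----------
    coords : DataFrame
        Columns ``lon``, ``lat``, indexed by county id.
    k : int
        Number of groups; must not exceed the number of distinct points.
    """
    points = coords[["lon", "lat"]].to_numpy(float)
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct coordinates")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
    labels = pd.Series(km.labels_ + 1, index=coords.index, name="group")
    return GroupAssignment(labels=labels, centroids=km.cluster_centers_, inertia=float(km.inertia_))
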