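"""Diel and tidal summary products.

Sunrise/sunset times (NOAA solar-position equations), the hour-by-day count
matrix used for visual inspection of diel structure, diel labeling
(day / night / crepuscular), and the tidal-stage by diel-period
cross-tabulation of mean hourly counts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tidalflux.timeseries_io import HourlyCountSeries
from tidalflux.tidal_model import TidalStageSeries

__all__ = [
    "SolarDay",
    "COBSCOOK_LAT",
    "COBSCOOK_LON",
    "solar_times",
    "solar_days_for_range",
    "hour_by_day_matrix",
    "diel_labels",
    "stage_diel_crosstab",
]

#: Default site: outer Cobscook Bay, Maine (longitude negative = west).
COBSCOOK_LAT = 44.9
COBSCOOK_LON = -67.0

DIEL_LABELS = ("day", "night", "crepuscular")


@dataclass(frozen=True)
class SolarDay:
    date: dt.date
    sunrise: pd.Timestamp  # site-local
    sunset: pd.Timestamp  # site-local

    def __post_init__(self) -> None:
        if self.sunset <= self.sunrise:
            raise ValueError("sunset must follow sunrise")


def solar_times(
    date: dt.date,
    lat: float = COBSCOOK_LAT,
    lon: float = COBSCOOK_LON,
    utc_offset: float = -4.0,
) -> SolarDay:
    """Sunrise and sunset for one date via the NOAA solar-position equations.

    ``lon`` is signed degrees east; ``utc_offset`` converts the UTC event
    times to site-local clock time.  Latitudes poleward of 66 deg, where the
    zenith crossing can vanish, are not supported.
    """
    if abs(lat) >= 66.0:
        raise ValueError(f"polar latitudes are not supported, got {lat}")
    eqtime, decl = _solar_position(date, utc_offset)
    lat_r = np.deg2rad(lat)
    zenith = np.deg2rad(90.833)  # refraction + solar disc radius
    cos_ha = np.cos(zenith) / (np.cos(lat_r) * np.cos(decl)) - np.tan(lat_r) * np.tan(decl)
    if not (-1.0 <= cos_ha <= 1.0):
        raise ValueError(f"sun does not rise/set at lat {lat} on {date}")
    ha_deg = np.rad2deg(np.arccos(cos_ha))
    noon_local_min = 720.0 - 4.0 * lon - eqtime + 60.0 * utc_offset
    base = pd.Timestamp(date.year, date.month, date.day)
    sunrise = base + pd.Timedelta(minutes=noon_local_min - 4.0 * ha_deg)
    sunset = base + pd.Timedelta(minutes=noon_local_min + 4.0 * ha_deg)
    return SolarDay(date=date, sunrise=sunrise, sunset=sunset)


def _solar_position(date: dt.date, utc_offset: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians) at local noon.

    NOAA solar-calculator formulation: Julian-century polynomial ephemeris
    for the sun's apparent longitude and obliquity.
    """
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    jd = int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.0 - utc_offset / 24.0
    jc = (jd - 2451545.0) / 36525.0
    gmls = np.deg2rad((280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0)
    gmas = np.deg2rad(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    seqc = np.deg2rad(
        np.sin(gmas) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * gmas) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * gmas) * 0.000289
    )
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = gmls + seqc - np.deg2rad(0.00569 + 0.00478 * np.sin(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = np.deg2rad(mean_obliq + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))
    vary = np.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * np.rad2deg(
        vary * np.sin(2 * gmls)
        - 2 * eeo * np.sin(gmas)
        + 4 * eeo * vary * np.sin(gmas) * np.cos(2 * gmls)
        - 0.5 * vary**2 * np.sin(4 * gmls)
        - 1.25 * eeo**2 * np.sin(2 * gmas)
    )
    return float(eqtime), float(decl)


def solar_days_for_range(
    start_date: dt.date,
    end_date: dt.date,
    lat: float = COBSCOOK_LAT,
    lon: float = COBSCOOK_LON,
    utc_offset: float = -4.0,
) -> dict[dt.date, SolarDay]:
    """Solar days for every date in [start_date, end_date]."""
    out = {}
    d = start_date
    while d <= end_date:
        out[d] = solar_times(d, lat, lon, utc_offset)
        d += dt.timedelta(days=1)
    return out


def hour_by_day_matrix(
    series: HourlyCountSeries, utc_offset: float = -4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """24 x D count matrix in site-local time, with provenance flags.

    Rows are local hour of day (0-23), columns local calendar dates.  Gap
    hours are NaN in the count matrix and flagged "missing"; filled hours
    carry their filled value and a "filled" flag, so imputed cells are never
    mistaken for observed zeros.
    """
    local_times = series.times + pd.Timedelta(hours=utc_offset)
    dates = local_times.date
    hours = local_times.hour
    day_index = pd.Index(sorted(set(dates)), name="date")
    counts = pd.DataFrame(np.nan, index=pd.RangeIndex(24, name="hour"), columns=day_index)
    flags = pd.DataFrame("absent", index=pd.RangeIndex(24, name="hour"), columns=day_index)
    flag_of = {
        "observed": "observed",
        "missing": "missing",
        "filled_median": "filled",
        "filled_linear": "filled",
        "filled_harmonic": "filled",
    }
    for v, obs, prov, d, h in zip(
        series.values, series.observed_mask, series.provenance, dates, hours
    ):
        counts.loc[h, d] = v
        flags.loc[h, d] = flag_of[prov]
    return counts, flags


def diel_labels(
    solar: Mapping[dt.date, SolarDay],
    times: pd.DatetimeIndex,
    crepuscular_halfwidth_hours: float = 1.5,
    utc_offset: float = -4.0,
) -> np.ndarray:
    """Label each hour day / night / crepuscular from the solar calendar.

    An hour is crepuscular when its midpoint falls within the half-width of
    sunrise or sunset; otherwise day between sunrise and sunset, else night.
    ``times`` are UTC; the solar calendar is site-local.
    """
    times = pd.DatetimeIndex(times)
    labels = np.empty(len(times), dtype=object)
    half = pd.Timedelta(hours=crepuscular_halfwidth_hours)
    for i, t in enumerate(times):
        mid_local = (t + pd.Timedelta(minutes=30) + pd.Timedelta(hours=utc_offset)).tz_localize(
            None
        ) if t.tzinfo else t + pd.Timedelta(minutes=30) + pd.Timedelta(hours=utc_offset)
        date = mid_local.date()
        if date not in solar:
            raise ValueError(f"solar calendar does not cover {date}")
        day = solar[date]
        if (
            crepuscular_halfwidth_hours > 0
            and (abs(mid_local - day.sunrise) <= half or abs(mid_local - day.sunset) <= half)
        ):
            labels[i] = "crepuscular"
        elif day.sunrise <= mid_local <= day.sunset:
            labels[i] = "day"
        else:
            labels[i] = "night"
    return labels


def stage_diel_crosstab(
    series: HourlyCountSeries,
    stages: TidalStageSeries,
    diel: np.ndarray,
    include_filled: bool = False,
) -> pd.DataFrame:
    """Mean hourly count in each (tidal stage, diel period) stratum.

    Imputed hours are excluded by default so filled values cannot feed back
    into the pattern summary.  Returns a tidy frame with columns stage,
    diel, mean_count, n_hours; empty strata are simply absent.
    """
    if len(stages.times) != len(series) or not (stages.times == series.times).all():
        raise ValueError("stage series must be aligned with the count series")
    if len(diel) != len(series):
        raise ValueError("diel labels must be aligned with the count series")
    usable = ~np.isnan(series.values)
    if not include_filled:
        usable &= series.observed_mask
    df = pd.DataFrame(
        {
            "stage": stages.stage[usable],
            "diel": np.asarray(diel, dtype=object)[usable],
            "count": series.values[usable],
        }
    )
    out = (
        df.groupby(["stage", "diel"], observed=True)["count"]
        .agg(mean_count="mean", n_hours="size")
        .reset_index()
    )
    return out
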