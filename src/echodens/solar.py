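"""NOAA-style solar position approximation for sunset/sunrise times.

Used when no user-supplied sun table is available.  Accuracy is a few
minutes, which is ample for defining survey nights.  All times are local
with a fixed UTC offset (no DST lookup).
"""

from __future__ import annotations

import datetime as dt
import math

import pandas as pd

__all__ = ["sun_times", "build_sun_table"]

_ZENITH_OFFICIAL = 90.833  # degrees; includes refraction + solar radius


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def sun_times(
    date: dt.date, latitude: float, longitude: float, utc_offset_hours: float
) -> tuple[dt.datetime, dt.datetime]:
    """Return (sunrise, sunset) as naive local datetimes for the given day.

    ``longitude`` is positive east; ``utc_offset_hours`` is the fixed local
    offset from UTC.
    """
    jd = _julian_day(date)
    jc = (jd - 2451545.0) / 36525.0

    geom_mean_long = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m_rad = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(m_rad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m_rad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m_rad) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )

    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * math.radians(geom_mean_long))
        - 2 * ecc * math.sin(m_rad)
        + 4 * ecc * var_y * math.sin(m_rad) * math.cos(2 * math.radians(geom_mean_long))
        - 0.5 * var_y**2 * math.sin(4 * math.radians(geom_mean_long))
        - 1.25 * ecc**2 * math.sin(2 * m_rad)
    )

    lat_rad = math.radians(latitude)
    decl_rad = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_ZENITH_OFFICIAL)) / (math.cos(lat_rad) * math.cos(decl_rad))
        - math.tan(lat_rad) * math.tan(decl_rad)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(
            f"sun does not rise/set at latitude {latitude} on {date} (polar day/night)"
        )
    ha = math.degrees(math.acos(cos_ha))

    solar_noon_min = 720.0 - 4.0 * longitude - eq_time + utc_offset_hours * 60.0
    sunrise_min = solar_noon_min - ha * 4.0
    sunset_min = solar_noon_min + ha * 4.0

    base = dt.datetime.combine(date, dt.time())
    return (
        base + dt.timedelta(minutes=sunrise_min),
        base + dt.timedelta(minutes=sunset_min),
    )


def build_sun_table(
    dates: list[dt.date], latitude: float, longitude: float, utc_offset_hours: float
) -> pd.DataFrame:
    """Sun table (date, sunset, sunrise) for survey nights.

    Each row describes the *night* starting on ``date``: sunset of that day
    and sunrise of the following morning.
    """
    rows = []
    for d in dates:
        _, sunset = sun_times(d, latitude, longitude, utc_offset_hours)
        sunrise_next, _ = sun_times(d + dt.timedelta(days=1), latitude, longitude, utc_offset_hours)
        rows.append({"date": pd.Timestamp(d), "sunset": sunset, "sunrise": sunrise_next})
    return pd.DataFrame(rows)
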