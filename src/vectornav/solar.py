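"""Solar ephemeris: azimuth/elevation and sunset times.

Implements the standard low-precision solar position algorithm (geometric
mean longitude / anomaly -> equation of center -> apparent ecliptic
longitude -> declination and equation of time -> local hour angle), the
one used by common almanac calculators.  Accuracy is of order 0.01-0.1
degrees over 1950-2050, far below the ~5-degree granularity of
orientation-cage bearings.

All instants are UTC; naive datetimes are interpreted as UTC.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timedelta, timezone

import numpy as np

from .geometry import GeoPosition


class CircumpolarError(ValueError):
    """The sun does not cross the horizon on this date at this latitude."""


@dataclass(frozen=True)
class SolarPosition:
    """Topocentric solar direction (refraction-free).

    azimuth   : degrees clockwise from geographic north, [0, 360)
    elevation : degrees above the geometric horizon, [-90, 90]
    """

    azimuth: float
    elevation: float


def _to_utc(instant: datetime) -> datetime:
    if instant.tzinfo is None:
        return instant.replace(tzinfo=timezone.utc)
    return instant.astimezone(timezone.utc)


def julian_day(instant: datetime) -> float:
    """UTC datetime -> Julian day number (float)."""
    t = _to_utc(instant)
    frac = (t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6) / 86400.0
    return t.toordinal() + 1721424.5 + frac


def _declination_eot(jd):
    """Solar declination (deg) and equation of time (minutes) at Julian day jd."""
    jc = (np.asarray(jd, dtype=float) - 2451545.0) / 36525.0
    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = np.radians(m)
    c = (
        np.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    lam_app = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.degrees(np.arcsin(np.sin(eps) * np.sin(lam_app)))
    y = np.tan(eps / 2.0) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * e * np.sin(mr)
        + 4.0 * e * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y**2 * np.sin(4 * l0r)
        - 1.25 * e**2 * np.sin(2 * mr)
    )
    return decl, eot


def sun_altaz_arrays(lat, lon, jd):
    """Vectorized azimuth/elevation (degrees) for arrays of lat, lon, Julian day."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    jd = np.asarray(jd, dtype=float)
    decl, eot = _declination_eot(jd)
    minutes_utc = (jd + 0.5 - np.floor(jd + 0.5)) * 1440.0
    tst = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)
    hour_angle = np.radians(tst / 4.0 - 180.0)
    phi = np.radians(lat)
    dr = np.radians(decl)
    north = np.sin(dr) * np.cos(phi) - np.cos(dr) * np.cos(hour_angle) * np.sin(phi)
    east = -np.cos(dr) * np.sin(hour_angle)
    up = np.sin(dr) * np.sin(phi) + np.cos(dr) * np.cos(hour_angle) * np.cos(phi)
    az = np.mod(np.degrees(np.arctan2(east, north)), 360.0)
    el = np.degrees(np.arcsin(np.clip(up, -1.0, 1.0)))
    return az, el


def sun_position(position: GeoPosition, instant: datetime) -> SolarPosition:
    """Solar azimuth/elevation at a position and UTC instant."""
    t = _to_utc(instant)
    if not 1950 <= t.year <= 2050:
        raise ValueError("instant outside the supported 1950-2050 window")
    az, el = sun_altaz_arrays(position.lat, position.lon, julian_day(t))
    return SolarPosition(azimuth=float(az), elevation=float(el))


def sunset_instant(position: GeoPosition, date: _date, horizon: float = 0.0) -> datetime:
    """UTC instant at which the sun's elevation crosses ``horizon`` going down.

    ``horizon`` defaults to the geometric horizon (0 degrees); pass -0.833
    for the conventional refracted-disk definition.  Resolved to 1 second
    by bracketing plus bisection over the half-day after local solar noon.
    """
    noon_utc = datetime(date.year, date.month, date.day, 12, 0, tzinfo=timezone.utc) - timedelta(
        hours=position.lon / 15.0
    )

    def elev(t: datetime) -> float:
        az, el = sun_altaz_arrays(position.lat, position.lon, julian_day(t))
        return float(el) - horizon

    # 5-minute bracketing grid from local noon to local midnight
    lo, hi = None, None
    t_prev, e_prev = noon_utc, elev(noon_utc)
    for k in range(1, 145):
        t_k = noon_utc + timedelta(minutes=5 * k)
        e_k = elev(t_k)
        if e_prev > 0.0 >= e_k:
            lo, hi = t_prev, t_k
            break
        t_prev, e_prev = t_k, e_k
    if lo is None:
        raise CircumpolarError(
            f"no sunset at lat={position.lat} on {date} (polar day or night)"
        )
    while (hi - lo).total_seconds() > 1.0:
        mid = lo + (hi - lo) / 2
        if elev(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return lo + (hi - lo) / 2
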