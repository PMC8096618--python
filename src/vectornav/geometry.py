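"""Spherical-Earth route geometry.

All route computations run on a sphere of mean radius 6371.0088 km.
Positions are geographic latitude/longitude in degrees; headings are
geographic (true-north-referenced) degrees clockwise, in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def wrap360(angle):
    """Normalize an angle (degrees) to [0, 360)."""
    return np.mod(angle, 360.0)


def wrap180(angle):
    """Normalize an angle (degrees) to (-180, 180]."""
    a = np.mod(angle, 360.0)
    return np.where(a > 180.0, a - 360.0, a) if np.ndim(a) else (a - 360.0 if a > 180.0 else a)


def angdiff(a, b):
    """Signed smallest difference a - b in degrees, in (-180, 180]."""
    return wrap180(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class GeoPosition:
    """A point on the spherical Earth.

    lat : degrees North, in [-90, 90]
    lon : degrees East, normalized to (-180, 180]
    """

    lat: float
    lon: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        lon = float(wrap180(float(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))
        object.__setattr__(self, "lon", lon)

    def as_tuple(self) -> tuple[float, float]:
        return (self.lat, self.lon)


# Kanaryarmiut Field Station, Yukon-Kuskokwim Delta (61 deg 21' N, 165 deg 08' W)
STUDY_SITE = GeoPosition(61.35, -165.1333)


def advance_arrays(lat, lon, heading, distance_km):
    """Great-circle direct problem, vectorized over numpy arrays (degrees)."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(heading, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    sin_lat2 = np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg)
    sin_lat2 = np.clip(sin_lat2, -1.0, 1.0)
    lat2 = np.arcsin(sin_lat2)
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * sin_lat2,
    )
    lat2_deg = np.degrees(lat2)
    lon2_deg = np.degrees(lon2)
    lon2_deg = np.mod(lon2_deg + 180.0, 360.0) - 180.0
    # keep the (-180, 180] convention: map -180 to +180
    lon2_deg = np.where(lon2_deg == -180.0, 180.0, lon2_deg)
    return lat2_deg, lon2_deg


def advance(position: GeoPosition, heading: float, distance_km: float) -> GeoPosition:
    """Destination of a great-circle step of `distance_km` along `heading`."""
    if distance_km < 0:
        raise ValueError("distance must be >= 0")
    lat2, lon2 = advance_arrays(position.lat, position.lon, heading, distance_km)
    return GeoPosition(float(lat2), float(lon2))


def gc_distance_km(a, b) -> float:
    """Great-circle distance (km); accepts GeoPositions or (lat, lon) arrays."""
    lat1, lon1 = (a.lat, a.lon) if isinstance(a, GeoPosition) else a
    lat2, lon2 = (b.lat, b.lon) if isinstance(b, GeoPosition) else b
    p1, p2 = np.radians(np.asarray(lat1, float)), np.radians(np.asarray(lat2, float))
    dlam = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    dphi = p2 - p1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def gc_bearing(origin, destination) -> float:
    """Initial great-circle bearing from origin to destination, degrees in [0, 360)."""
    lat1, lon1 = (origin.lat, origin.lon) if isinstance(origin, GeoPosition) else origin
    lat2, lon2 = (
        (destination.lat, destination.lon)
        if isinstance(destination, GeoPosition)
        else destination
    )
    p1, p2 = np.radians(float(lat1)), np.radians(float(lat2))
    dlam = np.radians(float(lon2) - float(lon1))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return float(wrap360(np.degrees(np.arctan2(y, x))))


def rhumb_course(origin: GeoPosition, destination: GeoPosition) -> float:
    """Constant compass course (loxodrome bearing) from origin to destination.

    Uses the Mercator-projected latitude difference and the shorter longitude
    arc, so a trans-Pacific westward goal yields a westward (SW) course.
    """
    if origin.as_tuple() == destination.as_tuple():
        raise ValueError("origin and destination coincide")
    if abs(origin.lat) >= 90.0 or abs(destination.lat) >= 90.0:
        raise ValueError("rhumb course undefined at the poles")
    psi1 = np.log(np.tan(np.pi / 4.0 + np.radians(origin.lat) / 2.0))
    psi2 = np.log(np.tan(np.pi / 4.0 + np.radians(destination.lat) / 2.0))
    dlon = np.radians(angdiff(destination.lon, origin.lon))
    return float(wrap360(np.degrees(np.arctan2(dlon, psi2 - psi1))))
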