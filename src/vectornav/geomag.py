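"""Geomagnetic reference field: declination, inclination, intensity, isoclines.

Synthesizes the main geomagnetic field from the vendored Schmidt
semi-normalized Gauss coefficient table (definitive epochs 2005.0 and
2010.0, linear interpolation in between), following the standard
spherical-harmonic expansion of the internal scalar potential

    V = a * sum_n (a/r)^(n+1) * sum_m [g_nm cos(m*lon) + h_nm sin(m*lon)] * P_nm(cos(colat))

evaluated in geocentric coordinates and rotated into the local geodetic
(north, east, down) frame.  An ``axial_dipole`` mode provides the textbook
dipole field (zero declination, tan(inclination) = 2 tan(latitude)), which
is useful for analytic tests and for isolating declination effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import GeoPosition, wrap360

# Geomagnetic reference radius (km) used by the spherical-harmonic expansion.
REFERENCE_RADIUS_KM = 6371.2
# WGS84 ellipsoid, for the geodetic <-> geocentric conversion only.
_WGS84_A = 6378.137
_WGS84_B = 6356.752314245

EPOCH_MIN = 2005.0
EPOCH_MAX = 2010.0

# Epoch used throughout for replicating the Alaska autumn-2005 field season
# (early September 2005).
STUDY_EPOCH = 2005.67


class FieldModelError(ValueError):
    pass


@dataclass(frozen=True)
class FieldVector:
    """Local geomagnetic field elements.

    declination : degrees, positive East of geographic north
    inclination : degrees, positive downward (dip angle)
    horizontal_intensity, total_intensity : nT
    """

    declination: float
    inclination: float
    horizontal_intensity: float
    total_intensity: float


@dataclass(frozen=True)
class FieldModelConfig:
    """Which field model to evaluate.

    model : 'spherical_harmonic' (vendored reference coefficients) or
            'axial_dipole' (analytic geocentric axial dipole)
    nmax  : truncation degree for the spherical-harmonic model (<= 13)
    """

    model: str = "spherical_harmonic"
    nmax: int = 13

    def __post_init__(self):
        if self.model not in ("spherical_harmonic", "axial_dipole"):
            raise FieldModelError(f"unknown field model {self.model!r}")
        if not 1 <= self.nmax <= 13:
            raise FieldModelError("nmax must be in [1, 13]")


_COEFFS = None


def _load_coefficients():
    global _COEFFS
    if _COEFFS is None:
        nmax = 13
        g0 = np.zeros((nmax + 1, nmax + 1))
        g1 = np.zeros((nmax + 1, nmax + 1))
        h0 = np.zeros((nmax + 1, nmax + 1))
        h1 = np.zeros((nmax + 1, nmax + 1))
        text = (
            resources.files("vectornav.data").joinpath("dgrf_main_field.txt").read_text()
        )
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, n, m, v05, v10 = line.split()
            n, m = int(n), int(m)
            if kind == "g":
                g0[n, m], g1[n, m] = float(v05), float(v10)
            else:
                h0[n, m], h1[n, m] = float(v05), float(v10)
        _COEFFS = (g0, g1, h0, h1)
    return _COEFFS


def _coeffs_at_epoch(epoch: float):
    if not EPOCH_MIN <= epoch <= EPOCH_MAX:
        raise FieldModelError(
            f"epoch {epoch} outside the vendored model's validity window "
            f"[{EPOCH_MIN}, {EPOCH_MAX}]"
        )
    g0, g1, h0, h1 = _load_coefficients()
    w = (epoch - EPOCH_MIN) / (EPOCH_MAX - EPOCH_MIN)
    return g0 + w * (g1 - g0), h0 + w * (h1 - h0)


def _geodetic_to_geocentric(lat_deg):
    """Geodetic latitude (deg) -> (geocentric radius km, geocentric latitude rad)."""
    phi = np.radians(lat_deg)
    c, s = np.cos(phi), np.sin(phi)
    a2, b2 = _WGS84_A**2, _WGS84_B**2
    r = np.sqrt((a2**2 * c**2 + b2**2 * s**2) / (a2 * c**2 + b2 * s**2))
    phi_gc = np.arctan2(b2 * s, a2 * c)
    return r, phi_gc


def _schmidt_legendre(nmax, x, s):
    """Schmidt semi-normalized P_nm(x) and dP_nm/dtheta, x=cos(theta), s=sin(theta).

    Returns arrays P, dP of shape (nmax+1, nmax+1) + x.shape.
    """
    shape = (nmax + 1, nmax + 1) + np.shape(x)
    P = np.zeros(shape)
    dP = np.zeros(shape)
    P[0, 0] = 1.0
    for n in range(1, nmax + 1):
        for m in range(0, n + 1):
            if n == m:
                fac = 1.0 if n == 1 else np.sqrt((2 * n - 1) / (2.0 * n))
                P[n, n] = fac * s * P[n - 1, n - 1]
                dP[n, n] = fac * (x * P[n - 1, n - 1] + s * dP[n - 1, n - 1])
            else:
                root = np.sqrt(n**2 - m**2)
                prev2 = P[n - 2, m] if n >= 2 else 0.0
                dprev2 = dP[n - 2, m] if n >= 2 else 0.0
                root2 = np.sqrt((n - 1) ** 2 - m**2) if n >= 2 else 0.0
                P[n, m] = ((2 * n - 1) * x * P[n - 1, m] - root2 * prev2) / root
                dP[n, m] = (
                    (2 * n - 1) * (x * dP[n - 1, m] - s * P[n - 1, m]) - root2 * dprev2
                ) / root
    return P, dP


def synth_field_arrays(lat, lon, epoch, nmax=13):
    """Field components (north, east, down) in nT, vectorized over lat/lon arrays.

    Latitude is geodetic; the expansion is evaluated geocentrically and
    rotated back into the geodetic frame.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    g, h = _coeffs_at_epoch(float(epoch))
    r, phi_gc = _geodetic_to_geocentric(lat)
    theta = np.pi / 2.0 - phi_gc  # geocentric colatitude
    x, sθ = np.cos(theta), np.sin(theta)
    P, dP = _schmidt_legendre(nmax, x, sθ)

    lam = np.radians(lon)
    ratio = REFERENCE_RADIUS_KM / r
    br = np.zeros(np.shape(lat))
    bt = np.zeros(np.shape(lat))
    bp = np.zeros(np.shape(lat))
    # guard the 1/sin(theta) factor near the geographic poles
    s_safe = np.where(np.abs(sθ) < 1e-10, 1e-10, sθ)
    for n in range(1, nmax + 1):
        rad = ratio ** (n + 2)
        for m in range(0, n + 1):
            cm, sm = np.cos(m * lam), np.sin(m * lam)
            gh_c = g[n, m] * cm + h[n, m] * sm
            br = br + (n + 1) * rad * gh_c * P[n, m]
            bt = bt - rad * gh_c * dP[n, m]
            if m > 0:
                bp = bp + rad * m * (g[n, m] * sm - h[n, m] * cm) * P[n, m] / s_safe
    # geocentric components: north = -B_theta, east = B_phi, down = -B_r
    xn, ye, zd = -bt, bp, -br
    # rotate from geocentric to geodetic frame
    psi = np.radians(lat) - phi_gc
    cd, sd = np.cos(psi), np.sin(psi)
    north = xn * cd + zd * sd
    down = zd * cd - xn * sd
    return north, ye, down


def _dipole_elements(lat):
    """Axial-dipole field elements; lat in degrees (geomagnetic == geographic)."""
    g10 = _load_coefficients()[0][1, 0]  # ~ -29555 nT at 2005
    b0 = abs(g10)
    phi = np.radians(np.asarray(lat, dtype=float))
    north = b0 * np.cos(phi)
    down = 2.0 * b0 * np.sin(phi)
    east = np.zeros_like(north)
    return north, east, down


def field_components(lat, lon, epoch, config: FieldModelConfig):
    """(north, east, down) nT arrays for either field model."""
    if config.model == "axial_dipole":
        return _dipole_elements(lat)
    return synth_field_arrays(lat, lon, epoch, nmax=config.nmax)


def declination_inclination(lat, lon, epoch, config: FieldModelConfig):
    """Vectorized declination and inclination (degrees)."""
    north, east, down = field_components(lat, lon, epoch, config)
    decl = np.degrees(np.arctan2(east, north))
    incl = np.degrees(np.arctan2(down, np.hypot(north, east)))
    return decl, incl


def field_at(position: GeoPosition, epoch: float, config: FieldModelConfig) -> FieldVector:
    """Evaluate the chosen field model at a position and decimal-year epoch."""
    north, east, down = field_components(position.lat, position.lon, epoch, config)
    north, east, down = float(north), float(east), float(down)
    hor = float(np.hypot(north, east))
    return FieldVector(
        declination=float(np.degrees(np.arctan2(east, north))),
        inclination=float(np.degrees(np.arctan2(down, hor))),
        horizontal_intensity=hor,
        total_intensity=float(np.sqrt(north**2 + east**2 + down**2)),
    )


def inclination_gradient(position: GeoPosition, epoch: float, config: FieldModelConfig,
                         step_deg: float = 0.1):
    """Central-difference gradient of inclination in deg/km (east, north axes)."""
    lat, lon = position.lat, position.lon
    km_per_deg = 2.0 * np.pi * 6371.0088 / 360.0
    lats = np.array([lat, lat, lat - step_deg, lat + step_deg])
    lons = np.array([lon - step_deg, lon + step_deg, lon, lon])
    _, incl = declination_inclination(lats, lons, epoch, config)
    d_east = (incl[1] - incl[0]) / (2.0 * step_deg * km_per_deg * np.cos(np.radians(lat)))
    d_north = (incl[3] - incl[2]) / (2.0 * step_deg * km_per_deg)
    return float(d_east), float(d_north)


def isocline_heading(position: GeoPosition, epoch: float, branch: str,
                     config: FieldModelConfig, step_deg: float = 0.1) -> float:
    """Geographic heading tangent to the local constant-inclination contour.

    The tangent is perpendicular to the inclination gradient; ``branch``
    ('NW' or 'SE') selects which of the two antipodal tangents to return
    (the one nearer the named quadrant).  The two branches differ by
    exactly 180 degrees.
    """
    if branch not in ("NW", "SE"):
        raise ValueError("branch must be 'NW' or 'SE'")
    de, dn = inclination_gradient(position, epoch, config, step_deg=step_deg)
    mag = np.hypot(de, dn)
    if mag < 1e-7:
        raise FieldModelError(
            "inclination gradient vanishes here (magnetic pole neighborhood); "
            "isocline heading undefined"
        )
    grad_az = np.degrees(np.arctan2(de, dn))
    t1 = wrap360(grad_az + 90.0)
    t2 = wrap360(grad_az - 90.0)
    target = 315.0 if branch == "NW" else 135.0
    d1 = abs((t1 - target + 180.0) % 360.0 - 180.0)
    d2 = abs((t2 - target + 180.0) % 360.0 - 180.0)
    return float(t1 if d1 <= d2 else t2)
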