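"""Planar projection and geodesic distance on the WGS84 ellipsoid.

The state-space model operates on a Cartesian plane in km. Geographic
coordinates are projected with the WGS84 World Mercator projection
(EPSG:3395, ellipsoidal Mercator) and the resulting eastings/northings are
divided by 1000 so all downstream distances, variances and speeds are in km.

Mercator northing diverges at the poles, so latitudes are restricted to an
open band (|lat| < 89.9 deg); out-of-band input raises rather than clamping,
because silent clamping corrupts distances.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

# WGS84 ellipsoid
WGS84_A = 6378137.0           # semi-major axis, m
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)   # first eccentricity squared
WGS84_E = np.sqrt(WGS84_E2)

LAT_BAND = 89.9  # degrees; Mercator y diverges at the poles


class GeoPoint(NamedTuple):
    """Geographic position: decimal degrees east / north."""

    lon: float
    lat: float


class PlanePoint(NamedTuple):
    """EPSG:3395 position in km (easting / northing divided by 1000)."""

    x: float
    y: float


def _check_lat(lat: np.ndarray, context: str = "") -> None:
    lat = np.asarray(lat, dtype=float)
    bad = ~(np.abs(lat) < LAT_BAND)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"latitude {np.atleast_1d(lat)[idx]!r} outside the Mercator band "
            f"(|lat| < {LAT_BAND}){' in ' + context if context else ''} "
            f"(record index {idx})"
        )


def project(lon, lat):
    """EPSG:3395 forward projection, returning km.

    Accepts scalars or arrays; longitudes are used as given (see
    :func:`unwrap_lon` for antimeridian handling before projection).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    _check_lat(lat, "project")
    lam = np.radians(lon)
    phi = np.radians(lat)
    x = WGS84_A * lam
    esin = WGS84_E * np.sin(phi)
    # isometric latitude: y = a * ln( tan(pi/4 + phi/2) * ((1-e sin)/(1+e sin))^(e/2) )
    y = WGS84_A * (
        np.log(np.tan(np.pi / 4.0 + phi / 2.0))
        + (WGS84_E / 2.0) * np.log((1.0 - esin) / (1.0 + esin))
    )
    if x.ndim == 0:
        return PlanePoint(float(x) / 1000.0, float(y) / 1000.0)
    return x / 1000.0, y / 1000.0


def unproject(x, y):
    """Inverse EPSG:3395 (km in, degrees out).

    The latitude inverse has no closed form; fixed-point iteration on the
    conformal-latitude relation converges quadratically and is run to 1e-12
    radians (well below the 1e-9 degree round-trip contract).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite plane coordinates")
    lam = (x * 1000.0) / WGS84_A
    t = np.exp(-(y * 1000.0) / WGS84_A)
    phi = np.pi / 2.0 - 2.0 * np.arctan(t)
    for _ in range(15):
        esin = WGS84_E * np.sin(phi)
        phi_new = np.pi / 2.0 - 2.0 * np.arctan(
            t * ((1.0 - esin) / (1.0 + esin)) ** (WGS84_E / 2.0)
        )
        if np.all(np.abs(phi_new - phi) < 1e-12):
            phi = phi_new
            break
        phi = phi_new
    lon = np.degrees(lam)
    lat = np.degrees(phi)
    if lon.ndim == 0:
        return GeoPoint(float(lon), float(lat))
    return lon, lat


def unwrap_lon(lon: np.ndarray) -> np.ndarray:
    """Unwrap a track's longitudes so consecutive fixes differ by < 180 deg.

    Mercator x is discontinuous at the antimeridian; tracks crossing it are
    unwrapped (values may leave [-180, 180]) before projection and re-wrapped
    with :func:`wrap_lon` on output.
    """
    lon = np.asarray(lon, dtype=float)
    if lon.size == 0:
        return lon.copy()
    return np.degrees(np.unwrap(np.radians(lon)))


def wrap_lon(lon):
    """Wrap longitudes back into [-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = ((lon + 180.0) % 360.0) - 180.0
    # keep +180 as +180 rather than -180
    wrapped = np.where((wrapped == -180.0) & (lon > 0), 180.0, wrapped)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def geodesic_km(lon1, lat1, lon2, lat2, n_iter: int = 100):
    """Geodesic distance on the WGS84 ellipsoid in km (Vincenty inverse).

    Vectorised over array inputs. The Vincenty iteration can fail for nearly
    antipodal pairs; those elements fall back to the haversine great-circle
    on the mean WGS84 radius (error < 0.6%, irrelevant at antipodal scales
    for travel-rate screening).
    """
    lon1, lat1, lon2, lat2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    )
    scalar = lon1.ndim == 0
    lon1, lat1, lon2, lat2 = (np.atleast_1d(a) for a in (lon1, lat1, lon2, lat2))

    U1 = np.arctan((1.0 - WGS84_F) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1.0 - WGS84_F) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    converged = np.zeros(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(n_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(sin_sigma > 0, cosU1 * cosU2 * sin_lam / np.where(sin_sigma > 0, sin_sigma, 1.0), 0.0)
        cos_sq_alpha = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2sm = np.where(
                cos_sq_alpha > 0,
                cos_sigma - 2.0 * sinU1 * sinU2 / np.where(cos_sq_alpha > 0, cos_sq_alpha, 1.0),
                0.0,  # equatorial line
            )
        C = WGS84_F / 16.0 * cos_sq_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos_sq_alpha))
        lam_new = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (cos2sm + C * cos_sigma * (-1.0 + 2.0 * cos2sm**2))
        )
        converged = np.abs(lam_new - lam) < 1e-12
        lam = lam_new
        if np.all(converged):
            break

    u_sq = cos_sq_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = B * sin_sigma * (
        cos2sm
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - B / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    dist = WGS84_B * A * (sigma - delta_sigma) / 1000.0

    if not np.all(converged):
        dist = np.where(converged, dist, _haversine_km(lon1, lat1, lon2, lat2))
    coincident = (lon1 == lon2) & (lat1 == lat2)
    dist = np.where(coincident, 0.0, dist)
    return float(dist[0]) if scalar else dist


def _haversine_km(lon1, lat1, lon2, lat2):
    r_mean = (2.0 * WGS84_A + WGS84_B) / 3.0 / 1000.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * r_mean * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
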