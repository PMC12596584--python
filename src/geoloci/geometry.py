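"""Spherical-geometry helpers shared across modules.

All distances use the mean Earth radius R = 6371.0 km. Local planar
work (KDE bandwidths, k-means, interpolation jitter) uses an
equirectangular projection about the data centroid:
x = R·Δλ·cos φ₀, y = R·Δφ — adequate at the regional scales this
package targets and dependency-free.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

EARTH_RADIUS_KM: float = 6371.0


def _check_lonlat(lon: np.ndarray, lat: np.ndarray) -> None:
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise InputError("coordinates out of range (|lon|<=180, |lat|<=90)")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between lon/lat points in degrees.

    d = 2R·asin( sqrt( sin²(Δφ/2) + cos φ₁·cos φ₂·sin²(Δλ/2) ) )
    """
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def pairwise_haversine_km(lonlat: np.ndarray) -> np.ndarray:
    """Symmetric n × n great-circle distance matrix for an n × 2 lon/lat array."""
    lon = lonlat[:, 0][:, None]
    lat = lonlat[:, 1][:, None]
    return haversine_km(lon, lat, lonlat[:, 0][None, :], lonlat[:, 1][None, :])


def project_km(lonlat: np.ndarray, origin: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to km about ``origin`` (default: centroid).

    Returns (xy_km, origin_lonlat). Inverse is :func:`unproject_km`.
    """
    lonlat = np.asarray(lonlat, dtype=float)
    if origin is None:
        origin = lonlat.mean(axis=0)
    origin = np.asarray(origin, dtype=float)
    phi0 = np.radians(origin[1])
    x = EARTH_RADIUS_KM * np.radians(lonlat[:, 0] - origin[0]) * np.cos(phi0)
    y = EARTH_RADIUS_KM * np.radians(lonlat[:, 1] - origin[1])
    return np.column_stack([x, y]), origin


def unproject_km(xy: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project_km`; returns n × 2 lon/lat degrees."""
    xy = np.asarray(xy, dtype=float)
    origin = np.asarray(origin, dtype=float)
    phi0 = np.radians(origin[1])
    lon = origin[0] + np.degrees(xy[:, 0] / (EARTH_RADIUS_KM * np.cos(phi0)))
    lat = origin[1] + np.degrees(xy[:, 1] / EARTH_RADIUS_KM)
    return np.column_stack([lon, lat])


def slerp_lonlat(p1: np.ndarray, p2: np.ndarray, frac: float) -> np.ndarray:
    """Point at fraction ``frac`` along the great-circle segment p1→p2.

    Inputs and output are (lon, lat) in degrees.
    """
    def to_xyz(p):
        lam, phi = np.radians(p[0]), np.radians(p[1])
        return np.array(
            [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
        )

    a, b = to_xyz(np.asarray(p1, float)), to_xyz(np.asarray(p2, float))
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return np.asarray(p1, dtype=float).copy()
    v = (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)
    v /= np.linalg.norm(v)
    lon = np.degrees(np.arctan2(v[1], v[0]))
    lat = np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    return np.array([lon, lat])
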