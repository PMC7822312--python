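"""Spherical geometry primitives shared across the pipeline.

All distances are great-circle kilometres on a sphere of mean Earth radius
6371.0088 km; bearings are degrees clockwise from true north in (-180, 180].
Trips here span < 150 km, so a local tangent-plane approximation (used by the
simulator and for small rigid translations) is accurate to well under 1%.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(a, b) -> np.ndarray | float:
    """Haversine distance between (lon, lat) points, in km.

    Parameters
    ----------
    a, b : array-like
        ``(lon, lat)`` pairs in decimal degrees; broadcastable arrays of
        shape ``(..., 2)`` are accepted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def initial_bearing_deg(origin, target) -> np.ndarray | float:
    """Initial great-circle bearing from *origin* to *target*.

    Degrees clockwise from north, in (-180, 180]; positive = eastward.
    """
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    lon1, lat1 = np.radians(origin[..., 0]), np.radians(origin[..., 1])
    lon2, lat2 = np.radians(target[..., 0]), np.radians(target[..., 1])
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    brg = np.degrees(np.arctan2(y, x))
    # arctan2 yields (-180, 180]; map the -180 edge onto +180
    brg = np.where(brg <= -180.0, brg + 360.0, brg)
    return float(brg) if brg.ndim == 0 else brg


def cumulative_path_km(lon: np.ndarray, lat: np.ndarray) -> float:
    """Total great-circle path length over consecutive fixes, km."""
    pts = np.column_stack([lon, lat])
    if len(pts) < 2:
        return 0.0
    return float(np.sum(great_circle_km(pts[:-1], pts[1:])))


def to_local_km(lon, lat, ref_lon: float, ref_lat: float):
    """Project lon/lat to tangent-plane x (east), y (north) km around a reference."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    kx = EARTH_RADIUS_KM * np.cos(np.radians(ref_lat)) * np.pi / 180.0
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return (lon - ref_lon) * kx, (lat - ref_lat) * ky


def from_local_km(x, y, ref_lon: float, ref_lat: float):
    """Inverse of :func:`to_local_km`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    kx = EARTH_RADIUS_KM * np.cos(np.radians(ref_lat)) * np.pi / 180.0
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return ref_lon + x / kx, ref_lat + y / ky


def laea_xy_km(lon, lat, lon0: float, lat0: float):
    """Lambert azimuthal equal-area projection (spherical), km.

    Used for polygon areas; equal-area by construction so hull areas are
    projection-consistent when centred on the region of interest.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    cosc = np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(lon - lam0)
    k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(lat) - np.sin(phi0) * np.cos(lat) * np.cos(lon - lam0)
    )
    return x, y
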