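"""Spherical geometry helpers.

All distances are great-circle (haversine) distances on a sphere of radius
6,371,000 m.  Local displacements (GPS jitter, straight-line transitions)
use a local tangent-plane approximation, which is accurate to well under a
metre at the sub-kilometre scales involved.
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = ["EARTH_RADIUS_M", "haversine_m", "haversine_vec_m", "offset_latlon"]


def haversine_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in metres between two (lat, lon) points in degrees."""
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def haversine_vec_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorised haversine distance in metres; arguments in degrees."""
    lat1 = np.radians(np.asarray(lat1, dtype=float))
    lon1 = np.radians(np.asarray(lon1, dtype=float))
    lat2 = np.radians(np.asarray(lat2, dtype=float))
    lon2 = np.radians(np.asarray(lon2, dtype=float))
    h = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def offset_latlon(lat: float, lon: float, east_m, north_m):
    """Displace (lat, lon) by metres east/north in the local tangent plane.

    ``east_m``/``north_m`` may be scalars or arrays; returns (lat, lon) with
    matching shape.
    """
    dlat = np.asarray(north_m, dtype=float) / EARTH_RADIUS_M
    dlon = np.asarray(east_m, dtype=float) / (EARTH_RADIUS_M * math.cos(math.radians(lat)))
    return lat + np.degrees(dlat), lon + np.degrees(dlon)
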