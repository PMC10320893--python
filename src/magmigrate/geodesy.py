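"""Closed-form great-circle kinematics on a spherical Earth.

All positions are geographic degrees (latitude positive north, longitude
positive east); bearings are degrees clockwise from true north. The sphere
radius is 6371 km, matching the near-surface scale of the simulated flights.
Every function broadcasts over numpy arrays.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_step",
    "great_circle_distance",
    "initial_bearing",
    "normalize_lon",
    "wrap_angle",
]


def normalize_lon(lon):
    """Wrap longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = -((-lon + 180.0) % 360.0 - 180.0)
    return out


def wrap_angle(angle):
    """Wrap an angular difference into (-180, 180] degrees."""
    angle = np.asarray(angle, dtype=float)
    return -((-angle + 180.0) % 360.0 - 180.0)


def great_circle_step(lat, lon, bearing, distance_km):
    """Advance along the great circle leaving (lat, lon) at ``bearing``.

    Solves the spherical direct problem for the given arc length and returns
    ``(lat2, lon2)``; positions are normalized (longitude to (-180, 180]).
    Steps across a pole are handled by the closed form without special cases.
    """
    lat1 = np.deg2rad(np.asarray(lat, dtype=float))
    lon1 = np.deg2rad(np.asarray(lon, dtype=float))
    brg = np.deg2rad(np.asarray(bearing, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM

    sin_lat2 = np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg)
    sin_lat2 = np.clip(sin_lat2, -1.0, 1.0)
    lat2 = np.arcsin(sin_lat2)
    y = np.sin(brg) * np.sin(delta) * np.cos(lat1)
    x = np.cos(delta) - np.sin(lat1) * sin_lat2
    lon2 = lon1 + np.arctan2(y, x)
    return np.rad2deg(lat2), normalize_lon(np.rad2deg(lon2))


def great_circle_distance(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (haversine; numerically safe near 0)."""
    p1 = np.deg2rad(np.asarray(lat1, dtype=float))
    p2 = np.deg2rad(np.asarray(lat2, dtype=float))
    dp = p2 - p1
    dl = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 toward point 2.

    Degrees clockwise from true north in [0, 360). Undefined (returns the
    atan2 convention value 0) when the points coincide or are antipodal.
    """
    p1 = np.deg2rad(np.asarray(lat1, dtype=float))
    p2 = np.deg2rad(np.asarray(lat2, dtype=float))
    dl = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.rad2deg(np.arctan2(y, x)) % 360.0
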