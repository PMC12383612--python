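"""Spherical geodesy helpers: haversine distance and initial bearing.

All distances are great-circle on a sphere of radius 6371.0088 km (the
IUGG mean Earth radius); bearings are initial great-circle azimuths in
degrees clockwise from north.
"""

from __future__ import annotations

import numpy as np

from .grids import EARTH_RADIUS_KM

COMPASS_8 = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2)."""
    lon1, lat1, lon2, lat2 = map(np.radians,
                                 (np.asarray(lon1, dtype=float),
                                  np.asarray(lat1, dtype=float),
                                  np.asarray(lon2, dtype=float),
                                  np.asarray(lat2, dtype=float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def initial_bearing_deg(lon1, lat1, lon2, lat2) -> float:
    """Initial great-circle bearing from point 1 to point 2, in [0, 360)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def compass_8way(bearing_deg: float) -> str:
    """Nearest 8-way compass label (45 degree sectors centred on N, NE, ...)."""
    idx = int(np.round((bearing_deg % 360.0) / 45.0)) % 8
    return COMPASS_8[idx]
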