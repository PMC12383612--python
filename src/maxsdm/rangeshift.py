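"""Suitability-weighted range centroids and migration trajectories.

The centroid of the suitable range in each period is the probability- and
area-weighted mean coordinate of suitable cells; consecutive centroids form
track segments with great-circle distance, initial bearing, an 8-way compass
label, and a migration velocity assuming a fixed number of years between
periods (20 by default, matching consecutive bidecadal climate periods).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import compass_8way, haversine_km, initial_bearing_deg
from .grids import GridDef


@dataclass(frozen=True)
class Centroid:
    lon: float
    lat: float
    period: str = ""
    scenario: str = ""


@dataclass(frozen=True)
class TrackSegment:
    start: Centroid
    end: Centroid
    distance_km: float
    azimuth_deg: float | None   # None when start == end
    compass: str | None
    velocity_km_per_yr: float


def weighted_centroid(p_layer: np.ndarray, grid: GridDef,
                      threshold: float = 0.1, period: str = "",
                      scenario: str = "") -> Centroid:
    """Probability-and-area weighted mean coordinate of suitable cells.

    Weight of each cell with P >= threshold is P times its spherical area;
    coordinates are averaged in lon/lat directly.
    """
    p = np.asarray(p_layer, dtype=float)
    if p.shape != grid.shape:
        raise ValueError("layer shape does not match grid")
    suitable = np.isfinite(p) & (p >= threshold)
    if not suitable.any():
        raise ValueError("no cells at or above the suitability threshold")
    w = p[suitable] * grid.area_grid_km2()[suitable]
    rows, cols = np.nonzero(suitable)
    lons = grid.col_lons()[cols]
    lats = grid.row_lats()[rows]
    return Centroid(lon=float(np.average(lons, weights=w)),
                    lat=float(np.average(lats, weights=w)),
                    period=period, scenario=scenario)


def geodesic_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) pairs."""
    return haversine_km(a[0], a[1], b[0], b[1])


def azimuth(a: tuple[float, float], b: tuple[float, float],
            ) -> tuple[float, str] | None:
    """Initial bearing (degrees from north) and 8-way compass label, or
    None for coincident points."""
    if a == b:
        return None
    bearing = initial_bearing_deg(a[0], a[1], b[0], b[1])
    return bearing, compass_8way(bearing)


def build_track(centroids: list[Centroid], years_between: float = 20.0,
                ) -> tuple[list[TrackSegment], float]:
    """Consecutive track segments plus the cumulative baseline displacement
    (great-circle distance from the first centroid to the last)."""
    if len(centroids) < 2:
        raise ValueError("need at least 2 centroids")
    segments: list[TrackSegment] = []
    for a, b in zip(centroids[:-1], centroids[1:]):
        d = geodesic_km((a.lon, a.lat), (b.lon, b.lat))
        az = azimuth((a.lon, a.lat), (b.lon, b.lat))
        segments.append(TrackSegment(
            start=a, end=b, distance_km=d,
            azimuth_deg=None if az is None else az[0],
            compass=None if az is None else az[1],
            velocity_km_per_yr=d / years_between))
    first, last = centroids[0], centroids[-1]
    cumulative = geodesic_km((first.lon, first.lat), (last.lon, last.lat))
    return segments, cumulative


def track_table(segments: list[TrackSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scenario": s.end.scenario,
        "from_period": s.start.period, "to_period": s.end.period,
        "from_lon": s.start.lon, "from_lat": s.start.lat,
        "to_lon": s.end.lon, "to_lat": s.end.lat,
        "distance_km": s.distance_km, "azimuth_deg": s.azimuth_deg,
        "compass": s.compass, "velocity_km_per_yr": s.velocity_km_per_yr,
    } for s in segments])


def track_geojson(centroids: list[Centroid],
                  segments: list[TrackSegment]) -> dict:
    """Centroids as Points and the trajectory as a LineString."""
    features = [{
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [c.lon, c.lat]},
        "properties": {"period": c.period, "scenario": c.scenario},
    } for c in centroids]
    features.append({
        "type": "Feature",
        "geometry": {"type": "LineString",
                     "coordinates": [[c.lon, c.lat] for c in centroids]},
        "properties": {
            "segments": [{"distance_km": s.distance_km,
                          "azimuth_deg": s.azimuth_deg,
                          "compass": s.compass,
                          "velocity_km_per_yr": s.velocity_km_per_yr}
                         for s in segments]},
    })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
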