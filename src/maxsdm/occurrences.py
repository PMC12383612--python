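"""Occurrence records and grid-based spatial thinning.

Presence-only records are thinned to at most one per grid cell: within each
occupied cell the record closest (great-circle) to the cell center is kept.
This removes duplicate and clustered records at the raster's own resolution
before model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km
from .grids import EnvStack, GridDef

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceRecord:
    id: str
    lon: float
    lat: float
    species: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")


@dataclass
class OccurrenceSet:
    """Ordered presence records, optionally already thinned on a grid."""

    records: list[OccurrenceRecord] = field(default_factory=list)
    thinned: bool = False
    grid: GridDef | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("occurrence ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r.lon for r in self.records], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([r.lat for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [r.id for r in self.records],
            "species": [r.species for r in self.records],
            "longitude": self.lons,
            "latitude": self.lats,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "OccurrenceSet":
        records = [OccurrenceRecord(id=str(row["id"]),
                                    lon=float(row["longitude"]),
                                    lat=float(row["latitude"]),
                                    species=str(row.get("species", "")))
                   for _, row in df.iterrows()]
        return cls(records=records, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OccurrenceSet":
        return cls.from_frame(pd.read_csv(path), **kwargs)


def assign_cells(points: OccurrenceSet, grid: GridDef,
                 ) -> tuple[dict[str, tuple[int, int]], list[str]]:
    """Map each record id to its (row, col) grid cell.

    Uses the floor convention: a point on a shared interior edge belongs to
    the cell to its south/east; points exactly on the outer east/north
    boundary are clamped into the last cell.  Records outside the grid
    extent are returned in a rejected list instead of being dropped
    silently.

    Returns
    -------
    (assignments, rejected_ids)
    """
    assignments: dict[str, tuple[int, int]] = {}
    rejected: list[str] = []
    for rec in points.records:
        if not grid.contains(rec.lon, rec.lat):
            rejected.append(rec.id)
            continue
        row, col = grid.locate(rec.lon, rec.lat)
        assignments[rec.id] = (int(row), int(col))
    if rejected:
        log.warning("%d occurrence(s) outside grid extent", len(rejected))
    return assignments, rejected


def thin(points: OccurrenceSet, grid: GridDef,
         stack: EnvStack | None = None) -> OccurrenceSet:
    """Keep, per occupied grid cell, the record nearest the cell center.

    Distance is great-circle (haversine); ties are broken by the smallest
    record id.  When an environment stack is supplied, records falling on
    masked (no-data) cells are ineligible: a record must carry complete
    habitat information at its cell.  Output order is row-major scan order
    over occupied cells, so the result is reproducible regardless of the
    input ordering.  Thinning an already-thinned set on the same grid is an
    idempotent no-op.
    """
    assignments, rejected = assign_cells(points, grid)

    by_cell: dict[tuple[int, int], OccurrenceRecord] = {}
    masked_out = 0
    for rec in points.records:
        if rec.id not in assignments:
            continue
        cell = assignments[rec.id]
        if stack is not None and not stack.mask[cell]:
            masked_out += 1
            continue
        lon_c, lat_c = grid.cell_center(*cell)
        dist = haversine_km(rec.lon, rec.lat, lon_c, lat_c)
        incumbent = by_cell.get(cell)
        if incumbent is None:
            by_cell[cell] = rec
            continue
        lon_i, lat_i = grid.cell_center(*cell)
        d_inc = haversine_km(incumbent.lon, incumbent.lat, lon_i, lat_i)
        if dist < d_inc or (dist == d_inc and rec.id < incumbent.id):
            by_cell[cell] = rec

    retained = [by_cell[c] for c in sorted(by_cell)]
    log.info("thinning: %d records -> %d (one per occupied cell; "
             "%d outside extent, %d on masked cells)",
             len(points), len(retained), len(rejected), masked_out)
    return OccurrenceSet(records=retained, thinned=True, grid=grid)
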