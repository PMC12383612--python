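"""Regular lon/lat grids and named raster stacks.

All rasters in the pipeline live on a shared regular grid in geographic
coordinates (WGS84 decimal degrees) with square cells, row 0 at the northern
edge.  Layers are plain 2-D float arrays; a shared boolean mask marks the
valid (modelled) domain.  On-disk interchange uses the ESRI ASCII grid
format, the text raster format that niche-modelling toolchains exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEGREE = 111_195.0
#: default cell size: 2.5 arc-minutes, in degrees
CELL_2P5_ARCMIN = 2.5 / 60.0

NODATA = -9999.0


class GridError(ValueError):
    """Invalid grid definition or grid mismatch between layers."""


@dataclass(frozen=True)
class GridDef:
    """A regular lon/lat grid with square cells.

    Row 0 is the northernmost row; column 0 the westernmost column.
    """

    n_rows: int
    n_cols: int
    west: float
    north: float
    cell_size: float = CELL_2P5_ARCMIN

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise GridError(f"grid dimensions must be positive, got "
                            f"{self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_lats(self) -> np.ndarray:
        """Latitudes of cell centers, per row (north to south)."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def col_lons(self) -> np.ndarray:
        """Longitudes of cell centers, per column (west to east)."""
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return ((lon >= self.west) & (lon <= self.east)
                & (lat >= self.south) & (lat <= self.north))

    def locate(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) by the floor convention.

        Points on an interior cell edge belong to the cell to the
        south/east; points exactly on the east/north outer boundary are
        clamped into the last row/column.  Coordinates outside the extent
        raise; use :meth:`contains` to pre-filter.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if not np.all(self.contains(lon, lat)):
            raise GridError("point(s) outside grid extent")
        col = np.floor((lon - self.west) / self.cell_size).astype(int)
        row = np.floor((self.north - lat) / self.cell_size).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def cell_area_km2(self, row) -> np.ndarray:
        """Spherical area of a cell in the given row(s), in km^2.

        area = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)); identical
        for every column of the row.
        """
        row = np.asarray(row)
        phi_top = np.radians(self.north - row * self.cell_size)
        phi_bot = np.radians(self.north - (row + 1) * self.cell_size)
        dlam = np.radians(self.cell_size)
        return EARTH_RADIUS_KM ** 2 * dlam * (np.sin(phi_top) - np.sin(phi_bot))

    def area_grid_km2(self) -> np.ndarray:
        """n_rows x n_cols array of per-cell spherical areas in km^2."""
        per_row = self.cell_area_km2(np.arange(self.n_rows))
        return np.repeat(per_row[:, None], self.n_cols, axis=1)


@dataclass
class EnvStack:
    """Named raster layers sharing one grid and one validity mask."""

    grid: GridDef
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None  # True where valid

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GridError("mask shape does not match grid")
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise GridError(f"layer {name!r} shape {arr.shape} does not "
                                f"match grid {self.grid.shape}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def add_layer(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self.grid.shape:
            raise GridError(f"layer {name!r} shape mismatch")
        if name in self.layers:
            raise GridError(f"duplicate layer name {name!r}")
        self.layers[name] = values

    def values_at_cells(self, rows, cols,
                        names: list[str] | None = None) -> np.ndarray:
        """Sample layers at cell indices -> (n_points, n_layers) array."""
        names = names if names is not None else self.layer_names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def valid_values(self, names: list[str] | None = None) -> np.ndarray:
        """Layer values over all valid cells -> (n_valid, n_layers)."""
        names = names if names is not None else self.layer_names
        return np.column_stack([self.layers[n][self.mask] for n in names])

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.mask)

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(self.grid, {n: self.layers[n] for n in names},
                        self.mask.copy())


def write_ascii_grid(path, values: np.ndarray, grid: GridDef,
                     mask: np.ndarray | None = None,
                     nodata: float = NODATA) -> None:
    """Write one layer as an ESRI ASCII grid (.asc)."""
    out = np.array(values, dtype=float)
    if mask is not None:
        out = np.where(mask, out, nodata)
    header = (f"ncols {grid.n_cols}\n"
              f"nrows {grid.n_rows}\n"
              f"xllcorner {grid.west!r}\n"
              f"yllcorner {grid.south!r}\n"
              f"cellsize {grid.cell_size!r}\n"
              f"NODATA_value {nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridDef, np.ndarray]:
    """Read an ESRI ASCII grid -> (values, grid, mask)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise GridError(f"data shape {values.shape} does not match header "
                        f"({n_rows}, {n_cols})")
    cell = header["cellsize"]
    grid = GridDef(n_rows=n_rows, n_cols=n_cols,
                   west=header["xllcorner"],
                   north=header["yllcorner"] + n_rows * cell,
                   cell_size=cell)
    nodata = header.get("nodata_value", NODATA)
    mask = values != nodata
    return values, grid, mask
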