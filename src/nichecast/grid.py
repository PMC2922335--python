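"""Regular lon/lat grids and multi-layer climate stacks.

One grid convention is shared by every module: row 0 is the northernmost
row, cell (0, 0) sits at the grid's NW origin, coordinates are carried by
cell centers, and point-in-cell tests use half-open cell extents
[west, east) x (south, north].  All grids are in WGS84 decimal degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

EARTH_RADIUS_KM = 6371.0088


class GridMismatchError(ValueError):
    """Two grids that must be identical are not."""


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular lon/lat raster.

    Parameters
    ----------
    n_rows, n_cols
        Cell counts; at least 2 each for a usable landscape.
    cell_size
        Cell edge length in decimal degrees (default mirrors the 1-km
        bioclim grids: 0.0083 degrees).
    origin
        (lon, lat) of the NW *corner* of cell (0, 0).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 0.0083
    origin: tuple[float, float] = (-85.0, 40.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid needs at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row, col):
        """Lon/lat of cell centers (vectorized over row/col arrays)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon0, lat0 = self.origin
        lon = lon0 + (col + 0.5) * self.cell_size
        lat = lat0 - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon and lat grids of every cell center, each shaped (n_rows, n_cols)."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def locate(self, lon, lat):
        """Map lon/lat points to (row, col).

        Uses half-open extents [west, east) x (south, north]: a point on a
        cell's west or north edge belongs to that cell.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lon0, lat0 = self.origin
        col = np.floor((lon - lon0) / self.cell_size).astype(int)
        # north edge inclusive -> ceil of (lat0 - lat)/size - 1, done via floor trick
        row = np.ceil((lat0 - lat) / self.cell_size).astype(int) - 1
        row = np.where(lat == lat0, 0, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        if not np.all(inside):
            raise ValueError("point(s) outside the grid extent")
        return row, col

    def require_same(self, other: "Grid") -> None:
        if self != other:
            raise GridMismatchError(f"grids differ: {self} vs {other}")


@dataclass
class ClimateStack:
    """A stack of gridded covariate layers sharing one grid and NODATA mask.

    ``values`` has shape (n_layers, n_rows, n_cols); ``valid`` is a boolean
    (n_rows, n_cols) mask, False where any layer is NODATA.
    """

    grid: Grid
    values: np.ndarray
    layer_names: list[str]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_layers, n_rows, n_cols)")
        if self.values.shape[1:] != self.grid.shape:
            raise GridMismatchError("layer shape does not match grid")
        if len(self.layer_names) != self.values.shape[0]:
            raise ValueError("one name per layer required")
        if self.valid is None:
            self.valid = np.isfinite(self.values).all(axis=0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise GridMismatchError("valid mask shape does not match grid")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def extract(self, rows, cols) -> np.ndarray:
        """Covariate matrix (n_points, n_layers) at the given cells."""
        return self.values[:, rows, cols].T

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            grid=self.grid,
            values=self.values.copy(),
            layer_names=list(self.layer_names),
            valid=self.valid.copy(),
        )


@dataclass(frozen=True)
class PointSet:
    """Georeferenced points snapped to cell centers of a shared grid.

    Used for both presences (``OccurrenceSet`` semantics, one species) and
    the pooled target-group background.  ``rows``/``cols`` index cells;
    duplicates per cell are retained unless ``dedupe`` collapses them.
    """

    grid: Grid
    rows: np.ndarray
    cols: np.ndarray
    species: str = ""
    for_modelling: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=int))
        object.__setattr__(self, "cols", np.asarray(self.cols, dtype=int))
        if self.rows.shape != self.cols.shape or self.rows.ndim != 1:
            raise ValueError("rows/cols must be matching 1-D arrays")
        if self.for_modelling and len(self.rows) <= 30:
            raise ValueError(
                f"species {self.species!r}: {len(self.rows)} points; "
                "modelling requires more than 30 point locations"
            )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def lon(self) -> np.ndarray:
        return self.grid.cell_center(self.rows, self.cols)[0]

    @property
    def lat(self) -> np.ndarray:
        return self.grid.cell_center(self.rows, self.cols)[1]

    def cell_ids(self) -> np.ndarray:
        return self.rows * self.grid.n_cols + self.cols

    def dedupe(self) -> "PointSet":
        """Collapse duplicate presences per cell (stable by first occurrence)."""
        _, idx = np.unique(self.cell_ids(), return_index=True)
        idx.sort()
        return replace(self, rows=self.rows[idx], cols=self.cols[idx],
                       for_modelling=False)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
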