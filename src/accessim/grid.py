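"""Shared raster-grid geometry and the georeferenced raster container.

All layers in one analysis (DEM, land cover, speeds, travel time, population,
urbanicity) share a single :class:`GridSpec`: a regular grid of square cells
in a planar CRS expressed in metres.  Row 0 is the northern (top) row, so the
array layout matches the usual raster convention; the grid origin is the
lower-left corner of the extent, as in the Esri ASCII grid header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = ["GridSpec", "Raster", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by every raster in an analysis.

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape; both at least 1.
    cell_size:
        Cell edge length in metres (default 30, the resolution at which
        travel time is accumulated).
    origin_x, origin_y:
        Planar coordinates (metres) of the lower-left corner of the extent.
    nodata:
        Sentinel written to file for missing cells; in memory missing cells
        are NaN (float rasters) or negative codes (integer rasters).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- extent ----------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def extent(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    # -- coordinate transforms ------------------------------------------
    def cell_center(self, row, col):
        """Planar coordinates of cell centres (vectorised)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y):
        """(row, col) of the cell containing planar point(s); no bounds clip."""
        x = np.asarray(x)
        y = np.asarray(y)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((y - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def center_mesh(self):
        """Arrays (X, Y) of shape (n_rows, n_cols) of all cell centres."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)

    def require_same(self, other: "GridSpec", names: Tuple[str, str] = ("a", "b")) -> None:
        if self != other:
            raise GridMismatchError(
                f"grid mismatch between {names[0]} ({self}) and {names[1]} ({other})"
            )


@dataclass
class Raster:
    """A single-band array tied to a :class:`GridSpec`.

    Float rasters use NaN for nodata in memory; +inf is reserved for
    "unreachable" in travel-time surfaces and is preserved by I/O.
    Integer-coded rasters (land cover, urbanicity, zone indices) use the
    ``data`` array directly with negative values as nodata.
    """

    grid: GridSpec
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "Raster":
        return Raster(self.grid, self.data.copy(), dict(self.meta))

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        if np.issubdtype(self.data.dtype, np.floating):
            return ~np.isnan(self.data)
        return self.data >= 0
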