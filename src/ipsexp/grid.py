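"""Grid geometry shared by every raster layer.

A :class:`GridSpec` fixes the geometry (shape, cell size, origin) and the
nodata mask for a set of co-registered layers.  The convention throughout the
package is:

* pixel-center registration: the center of pixel ``(row, col)`` sits at
  ``(origin_lon + (col + 0.5) * cell_size, origin_lat + (row + 0.5) * cell_size)``;
* row index increases northward (row 0 is the southernmost row);
* ``nodata_mask`` is ``True`` where a pixel carries no data; such pixels are
  excluded from every sum, mean and regression downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec"]


@dataclass
class GridSpec:
    """Geometry of a raster grid (pixel-center registration)."""

    n_rows: int
    n_cols: int
    cell_size: float = 1.0 / 6.0  # degrees; default ~10 arc-minutes
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    nodata_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("nodata_mask shape does not match grid shape")

    # -- basic properties -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_valid(self) -> int:
        """Number of non-nodata pixels."""
        return int((~self.nodata_mask).sum())

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, ``True`` where the pixel carries data."""
        return ~self.nodata_mask

    # -- coordinate arithmetic -------------------------------------------

    def lon_centers(self) -> np.ndarray:
        """Longitudes of column centers, length ``n_cols``."""
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, length ``n_rows``."""
        return self.origin_lat + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lat_grid(self) -> np.ndarray:
        """Per-pixel latitude (n_rows x n_cols)."""
        return np.broadcast_to(
            self.lat_centers()[:, None], (self.n_rows, self.n_cols)
        ).copy()

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to ``(row, col)`` indices with floor division.

        Indices may fall outside the grid; use :meth:`contains` to check.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((lat - self.origin_lat) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_of(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def center_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates of ``(row, col)``."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat + (row + 0.5) * self.cell_size
        return lon, lat

    # -- co-registration --------------------------------------------------

    def same_geometry(self, other: "GridSpec", *, tol: float = 1e-9) -> bool:
        """True when two grids are exactly co-registered (mask may differ)."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
        )

    def copy(self) -> "GridSpec":
        return GridSpec(
            self.n_rows,
            self.n_cols,
            self.cell_size,
            self.origin_lon,
            self.origin_lat,
            self.nodata_mask.copy(),
        )
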