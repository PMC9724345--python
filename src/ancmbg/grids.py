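"""Georeferenced regular grids in projected kilometre coordinates.

The package works on a single planar study area, so a raster is fully
described by its lower-left corner, a square cell size and a value matrix.
Rows are stored north-to-south (row 0 is the top row), matching the ESRI
ASCII grid convention used for on-disk interchange.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class GridSurface:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values
        2-D array, shape ``(nrows, ncols)``; row 0 is the northernmost row.
    x0, y0
        Coordinates (km) of the *lower-left corner* of the grid extent.
    res
        Cell size in km (cells are square).
    nodata
        Sentinel for missing cells (compared with ``==``).
    """

    values: np.ndarray
    x0: float
    y0: float
    res: float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.res <= 0:
            raise ValueError("resolution must be positive")

    # ------------------------------------------------------------------ shape
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (self.x0, self.y0,
                self.x0 + self.ncols * self.res,
                self.y0 + self.nrows * self.res)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.nodata

    # --------------------------------------------------------------- geometry
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xc, yc) 2-D arrays of cell-centre coordinates."""
        xc = self.x0 + (np.arange(self.ncols) + 0.5) * self.res
        yc = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.res
        return np.meshgrid(xc, yc)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col index of the cell containing each point (clipped to grid)."""
        col = np.clip(np.floor((np.asarray(x) - self.x0) / self.res).astype(int),
                      0, self.ncols - 1)
        row = np.clip(self.nrows - 1
                      - np.floor((np.asarray(y) - self.y0) / self.res).astype(int),
                      0, self.nrows - 1)
        return row, col

    def value_at(self, x, y):
        """Value of the cell containing (x, y); scalar or array."""
        row, col = self.index_of(np.asarray(x), np.asarray(y))
        return self.values[row, col]

    def copy_with(self, values: np.ndarray) -> "GridSurface":
        return GridSurface(np.asarray(values, dtype=float), self.x0, self.y0,
                           self.res, self.nodata)

    def full_like(self, fill: float) -> "GridSurface":
        return self.copy_with(np.full_like(self.values, fill))

    def same_geometry(self, other: "GridSurface", tol: float = 1e-9) -> bool:
        return (self.values.shape == other.values.shape
                and abs(self.x0 - other.x0) < tol
                and abs(self.y0 - other.y0) < tol
                and abs(self.res - other.res) < tol)

    # --------------------------------------------------------------------- IO
    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plain text, GIS-readable)."""
        header = (f"ncols {self.ncols}\n"
                  f"nrows {self.nrows}\n"
                  f"xllcorner {self.x0!r}\n"
                  f"yllcorner {self.y0!r}\n"
                  f"cellsize {self.res!r}\n"
                  f"NODATA_value {self.nodata!r}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "GridSurface":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(values, meta["xllcorner"], meta["yllcorner"],
                   meta["cellsize"], meta.get("nodata_value", NODATA))
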