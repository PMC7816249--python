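"""Lightweight georeferenced raster grid.

The pipeline operates on an abstract projected plane measured in kilometres.
Grids follow the usual GIS raster convention: row-major storage with the
origin at the top-left corner, cell-centre coordinates, and half-open cell
intervals.  Nodata cells are carried as NaN in memory and serialised with an
explicit sentinel in the ESRI ASCII grid format (the plain-text raster
interchange format understood by every GIS and by the standard
circuit-theory connectivity tools).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid"]


@dataclass
class RasterGrid:
    """A 2-D surface on a regular grid.

    Parameters
    ----------
    data:
        2-D float array; NaN marks nodata cells.
    x0, y0:
        Coordinates (km) of the lower-left corner of the grid (edge, not
        cell centre), matching the ``xllcorner``/``yllcorner`` header of the
        ASCII grid format.
    cell_size:
        Cell edge length in km (> 0, square cells).
    crs:
        Opaque coordinate-reference tag carried through for real-data use;
        never interpreted.
    """

    data: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    crs: str | None = None
    nodata: float = field(default=-9999.0, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- basic geometry -------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells holding data."""
        return np.isfinite(self.data)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid edges, km."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    def rowcol_to_xy(self, row, col):
        """Cell-centre coordinates of (row, col); row 0 is the top row."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def xy_to_rowcol(self, x, y):
        """Containing cell of a point; half-open intervals, no bounds clip."""
        x = np.asarray(x)
        y = np.asarray(y)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 + self.nrows * self.cell_size - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (x, y) of all cell centres, shaped like data."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.rowcol_to_xy(rows, cols)

    # -- construction helpers -------------------------------------------

    def like(self, data: np.ndarray) -> "RasterGrid":
        """New grid with the same georeferencing and fresh data."""
        if np.shape(data) != self.shape:
            raise ValueError("shape mismatch with template grid")
        return replace(self, data=np.asarray(data, dtype=float))

    def copy(self) -> "RasterGrid":
        return replace(self, data=self.data.copy())

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    # -- ASCII grid I/O --------------------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        """Serialise as an ESRI ASCII grid (plain text)."""
        out = np.where(self.valid, self.data, self.nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0:.10g}\n"
            f"yllcorner {self.y0:.10g}\n"
            f"cellsize {self.cell_size:.10g}\n"
            f"NODATA_value {self.nodata:.10g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path, crs: str | None = None) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) != 2 or not parts[0][0].isalpha():
                    fh.seek(pos)
                    break
                header[parts[0].lower()] = float(parts[1])
            body = np.loadtxt(fh, ndmin=2)
        nodata = header.get("nodata_value", -9999.0)
        data = np.where(body == nodata, np.nan, body)
        grid = cls(
            data=data,
            x0=header.get("xllcorner", 0.0),
            y0=header.get("yllcorner", 0.0),
            cell_size=header.get("cellsize", 1.0),
            crs=crs,
            nodata=nodata,
        )
        if "ncols" in header and grid.ncols != int(header["ncols"]):
            raise ValueError(f"{path}: ncols header does not match body")
        return grid
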