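"""Planar single-band rasters with plain-text (ESRI ASCII grid) I/O.

The whole pipeline works in a projected, planar coordinate system in metres.
A :class:`Raster` stores its band as a 2-D float array with row 0 at the
northern edge; missing cells are ``NaN`` in memory and the ``nodata`` value
on disk.

Cell ownership follows the half-open convention: a point with coordinates
``(x, y)`` belongs to the cell whose column is ``floor((x - x0)/cell)`` and
whose row is ``floor((y0 - y)/cell)``, so a point on a shared edge belongs
to the cell to its east / south.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "RasterError", "read_ascii_grid", "write_ascii_grid"]


class RasterError(ValueError):
    """Raised for invalid raster geometry or out-of-coverage queries."""


@dataclass
class Raster:
    """A single georeferenced band on a regular square grid.

    Parameters
    ----------
    data
        2-D array, row 0 northernmost. Stored as float64; NaN marks nodata.
    x0, y0
        Coordinates of the grid's north-west corner (metres).
    cell
        Cell side length in metres (> 0).
    """

    data: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell: float = 25.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise RasterError("raster data must be a non-empty 2-D array")
        if self.cell <= 0:
            raise RasterError("cell size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0 - self.nrows * self.cell,
            self.x0 + self.ncols * self.cell,
            self.y0,
        )

    def same_grid(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell - other.cell) <= tol
        )

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=float), self.x0, self.y0, self.cell, self.nodata)

    # -- point queries ------------------------------------------------------
    def index(self, x, y):
        """Row/column of the containing cell (half-open convention).

        Accepts scalars or arrays; raises :class:`RasterError` if any point
        lies outside the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - y) / self.cell).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            raise RasterError("point(s) outside raster coverage")
        return row, col

    def sample(self, x, y):
        """Band value at the containing cell of each point (NaN on nodata)."""
        row, col = self.index(x, y)
        return self.data[row, col]

    def cell_center(self, row, col):
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell
        return x, y

    # -- I/O ----------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        write_ascii_grid(self, path)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    path = Path(path)
    xll = raster.x0
    yll = raster.y0 - raster.nrows * raster.cell
    data = np.where(np.isnan(raster.data), raster.nodata, raster.data)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {xll:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {raster.cell:.6f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # headerless extras are not expected; stop at first data row
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float)
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise RasterError(f"grid shape {data.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    cell = header["cellsize"]
    y0 = header["yllcorner"] + nrows * cell
    return Raster(data, header["xllcorner"], y0, cell, nodata)
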