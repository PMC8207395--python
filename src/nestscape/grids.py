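"""Minimal raster container and ESRI ASCII grid I/O.

A :class:`Raster` is a rectangular grid of cells with a lower-left origin,
square cells, and an optional nodata code.  Row 0 of ``values`` is the *top*
row of the map (the ESRI ASCII convention), so the y coordinate of a cell
decreases with its row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A rectangular single-band raster with square cells.

    Parameters
    ----------
    values
        2-D array, row 0 at the top of the map.
    cell_size
        Side length of a cell in meters.
    xll, yll
        Coordinates of the lower-left corner of the grid, in meters.
    nodata
        Value marking missing cells, or ``None``.
    """

    values: np.ndarray
    cell_size: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid, in meters."""
        return (
            self.xll,
            self.yll,
            self.xll + self.n_cols * self.cell_size,
            self.yll + self.n_rows * self.cell_size,
        )

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        m = np.isfinite(self.values.astype(float))
        if self.nodata is not None:
            m &= self.values != self.nodata
        return m

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Map a point in map coordinates to its containing (row, col)."""
        col = int(np.floor((x - self.xll) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - self.yll) / self.cell_size))
        # points exactly on the top/right boundary belong to the last cell
        col = min(max(col, 0), self.n_cols - 1) if self._contains(x, y) else col
        row = min(max(row, 0), self.n_rows - 1) if self._contains(x, y) else row
        if not self._contains(x, y):
            raise ValueError(f"point ({x}, {y}) falls outside the raster extent {self.extent}")
        return row, col

    def _contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """A new raster sharing this grid's geometry."""
        return Raster(values, self.cell_size, self.xll, self.yll, nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    nodata = raster.nodata if raster.nodata is not None else -9999
    vals = np.where(raster.valid_mask(), raster.values, nodata)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.xll}\n"
        f"yllcorner {raster.yll}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid; integer-valued grids come back as integers."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        body = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid {path!r} is missing header field {key!r}")
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body shape {body.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    if np.all(np.isfinite(body)) and np.allclose(body, np.round(body)):
        body = body.astype(np.int64)
    nodata = header.get("nodata_value")
    return Raster(
        body,
        cell_size=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        nodata=nodata,
    )
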