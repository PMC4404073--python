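"""Regular raster grids with ESRI ASCII grid I/O.

A :class:`RasterGrid` is a regular cell grid in projected meters, used both
for gridded environmental exposures (the 200 m "data net") and for
interpolated coefficient surfaces. Values are stored row-major with row 0 the
*northernmost* row, matching the ESRI ASCII convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

NODATA_DEFAULT = -9999.0


@dataclass
class RasterGrid:
    """Regular grid of square cells.

    Parameters
    ----------
    x0, y0 : float
        Coordinates (meters) of the lower-left corner of the grid.
    cell_size : float
        Cell edge length in meters (200 by default in the exposure pipeline).
    values : ndarray of shape (n_rows, n_cols)
        Cell values; row 0 is the top (north) row. ``nodata`` marks missing.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray
    nodata: float = NODATA_DEFAULT

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @classmethod
    def empty(cls, x0, y0, cell_size, n_rows, n_cols, fill=0.0, nodata=NODATA_DEFAULT):
        return cls(x0, y0, cell_size, np.full((n_rows, n_cols), float(fill)), nodata)

    @classmethod
    def from_extent(cls, xmin, ymin, xmax, ymax, cell_size, fill=0.0):
        """Smallest grid of whole cells covering [xmin,xmax] x [ymin,ymax]."""
        n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size)))
        n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size)))
        return cls.empty(xmin, ymin, cell_size, n_rows, n_cols, fill)

    def cell_centers(self):
        """Return (X, Y) arrays of shape (n_rows, n_cols) of cell centers."""
        cs = self.cell_size
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * cs
        return np.meshgrid(xs, ys)

    def centers_flat(self):
        X, Y = self.cell_centers()
        return np.column_stack([X.ravel(), Y.ravel()])

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds real data."""
        return self.values != self.nodata

    def value_at(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); nodata outside the grid."""
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - self.y0) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return float(self.values[row, col])
        return float(self.nodata)

    def copy_with(self, values) -> "RasterGrid":
        return RasterGrid(self.x0, self.y0, self.cell_size, np.array(values, float), self.nodata)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0:.6f}\n"
        f"yllcorner {grid.y0:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in grid.values:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc). Accepts xllcorner or xllcenter."""
    header = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(parts)
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cs = header["cellsize"]
    x0 = header.get("xllcorner", header.get("xllcenter", 0.0) - cs / 2)
    y0 = header.get("yllcorner", header.get("yllcenter", 0.0) - cs / 2)
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    flat = [float(v) for parts in data_lines for v in parts]
    values = np.array(flat).reshape(n_rows, n_cols)
    return RasterGrid(x0, y0, cs, values, nodata)
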