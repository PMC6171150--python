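"""Planar raster grids, plain-text grid I/O and terrain derivatives.

All layers live on a single planar grid in metres (UTM-like; no geodesy).
Rasters are stored as 2-D numpy arrays with row 0 at the *north* edge, and
are exchanged on disk in the ESRI ASCII grid format (header lines
``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` followed by
whitespace-separated rows, north to south).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster: lower-left corner, square cell size, shape."""

    xll: float
    yll: float
    cell_size: float
    nrows: int
    ncols: int
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("raster must have at least one row and column")

    @property
    def width(self) -> float:
        return self.ncols * self.cell_size

    @property
    def height(self) -> float:
        return self.nrows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (self.xll, self.yll, self.xll + self.width, self.yll + self.height)

    def point_to_rowcol(self, x, y):
        """Row/column of the cell containing each point (0-based, row 0 north).

        Points must lie inside the extent; raises ``ValueError`` otherwise.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        bad = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({np.atleast_1d(x)[i]:.1f}, {np.atleast_1d(y)[i]:.1f}) "
                f"outside raster extent {self.extent}"
            )
        col = np.clip(((x - xmin) / self.cell_size).astype(int), 0, self.ncols - 1)
        row = np.clip(((ymax - y) / self.cell_size).astype(int), 0, self.nrows - 1)
        return row, col

    def cell_centers(self):
        """(x, y) coordinate arrays of every cell centre, shape (nrows, ncols)."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.yll + self.height - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class LandscapeStack:
    """Aligned covariate rasters: vegetation codes, elevation and the
    regional empirical timberline (RET), all on one :class:`Grid`.

    ``vegetation`` holds integer codes 1–25 (or the grid's nodata value);
    ``elevation`` and ``timberline`` are metres above sea level.
    """

    vegetation: np.ndarray
    elevation: np.ndarray
    timberline: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        shape = (self.grid.nrows, self.grid.ncols)
        for name in ("vegetation", "elevation", "timberline"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} raster shape {arr.shape} does not match grid {shape}"
                )
        veg = self.vegetation
        valid = veg != self.grid.nodata
        if valid.any():
            codes = veg[valid]
            if codes.min() < 1 or codes.max() > 25:
                raise ValueError("vegetation codes must be in 1..25 or nodata")


def write_ascii_grid(path: str | Path, array: np.ndarray, grid: Grid) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, np.asarray(array), fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, Grid]:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        array = np.loadtxt(fh)
    array = np.atleast_2d(array)
    grid = Grid(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        nodata=header.get("nodata_value", NODATA_DEFAULT),
    )
    if array.shape != (grid.nrows, grid.ncols):
        raise ValueError(f"grid body {array.shape} does not match header")
    return array, grid


def slope_aspect(elevation: np.ndarray, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (compass degrees) by Horn's 8-neighbour
    finite differences, cell-centre convention, row 0 = north edge.

    Aspect is the downslope compass direction in [0, 360): 0 = north,
    90 = east.  Cells with zero gradient get aspect 0 (they are classified
    as flat downstream from their slope).  Edge cells use replicate padding.
    """
    z = np.asarray(elevation, dtype=float)
    pad = np.pad(z, 1, mode="edge")
    c = grid.cell_size
    # Horn kernel: weights 1,2,1 on the three neighbours each side
    zr = pad[1:-1, 2:]
    zl = pad[1:-1, :-2]
    ztr, zbr = pad[:-2, 2:], pad[2:, 2:]
    ztl, zbl = pad[:-2, :-2], pad[2:, :-2]
    zt, zb = pad[:-2, 1:-1], pad[2:, 1:-1]
    dzdx = ((ztr + 2 * zr + zbr) - (ztl + 2 * zl + zbl)) / (8 * c)
    # y increases northwards but row index increases southwards
    dzdy = ((ztl + 2 * zt + ztr) - (zbl + 2 * zb + zbr)) / (8 * c)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope direction = -gradient; compass angle clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[(dzdx == 0) & (dzdy == 0)] = 0.0
    return slope, aspect
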