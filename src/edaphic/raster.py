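"""Minimal planar raster support: grids, rasterization, nearest resampling, TIFF I/O.

Rasters are single-band, square-celled and axis-aligned in a projected
(planar, metre-unit) coordinate system. Row 0 is the northernmost row.
Cell ownership is half-open so that no point ever belongs to two cells:
a point on a shared vertical edge belongs to the cell on its right, and a
point on a shared horizontal edge belongs to the cell directly below it.

Files are written as single-band TIFFs carrying the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, GDAL nodata) plus the CRS string in
the image description, so they open correctly in GIS software.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import shapely
import tifffile

__all__ = [
    "GridSpec",
    "Raster",
    "rasterize",
    "resample_nearest",
    "read_geotiff",
    "write_geotiff",
]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (origin at the top-left corner)."""

    x0: float
    y_top: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def x1(self) -> float:
        return self.x0 + self.ncols * self.cell

    @property
    def y_bottom(self) -> float:
        return self.y_top - self.nrows * self.cell

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y_top - (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); -1 marks points off the grid.

        Half-open ownership: x in [x0, x1), y in (y_bottom, y_top], with each
        cell owning its top and left edges.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((self.y_top - y) / self.cell).astype(int)
        # the top edge of the grid belongs to row 0
        row = np.where(np.asarray(self.y_top - y) == 0.0, 0, row)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        return np.where(bad, -1, row), np.where(bad, -1, col)

    def cell_box(self, row: int, col: int) -> shapely.Polygon:
        x = self.x0 + col * self.cell
        y = self.y_top - row * self.cell
        return shapely.box(x, y - self.cell, x + self.cell, y)

    def aligned_with(self, other: "GridSpec") -> bool:
        return (
            self.x0 == other.x0
            and self.y_top == other.y_top
            and self.cell == other.cell
            and self.shape == other.shape
        )


@dataclasses.dataclass
class Raster:
    """A single-band raster: a value array plus its grid geometry and CRS tag."""

    values: np.ndarray
    grid: GridSpec
    crs: str | None = None
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def sample(self, x, y, fill=None):
        """Nearest (containing-cell) sample at point coordinates."""
        if fill is None:
            fill = self.nodata
        row, col = self.grid.index_of(x, y)
        inside = row >= 0
        out = np.full(np.shape(row), fill, dtype=self.values.dtype)
        out[inside] = self.values[row[inside], col[inside]]
        return out


def rasterize(geoms, values, grid: GridSpec, fill, dtype=np.uint8) -> np.ndarray:
    """Burn polygon values onto a grid by cell-centre membership.

    Later geometries overwrite earlier ones where they overlap. A cell is
    assigned to a polygon when the polygon intersects the cell centre, which
    for a tessellation gives exact areas whenever polygon edges align with
    cell edges (centres are never on edges).
    """
    geoms = list(geoms)
    values = list(values)
    if len(geoms) != len(values):
        raise ValueError("geoms and values must have equal length")
    out = np.full(grid.shape, fill, dtype=dtype)
    X, Y = grid.cell_centers()
    for geom, val in zip(geoms, values):
        minx, miny, maxx, maxy = shapely.bounds(geom)
        c0 = max(0, int(math.floor((minx - grid.x0) / grid.cell)))
        c1 = min(grid.ncols, int(math.ceil((maxx - grid.x0) / grid.cell)) + 1)
        r0 = max(0, int(math.floor((grid.y_top - maxy) / grid.cell)))
        r1 = min(grid.nrows, int(math.ceil((grid.y_top - miny) / grid.cell)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        hit = shapely.intersects_xy(geom, X[r0:r1, c0:c1], Y[r0:r1, c0:c1])
        out[r0:r1, c0:c1][hit] = val
    return out


def resample_nearest(src: Raster, grid: GridSpec, fill=None) -> Raster:
    """Resample a raster onto another grid by nearest-neighbour (containing cell)."""
    if fill is None:
        fill = src.nodata if src.nodata is not None else 0
    X, Y = grid.cell_centers()
    values = src.sample(X, Y, fill=fill)
    return Raster(values=values, grid=grid, crs=src.crs, nodata=src.nodata)


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(path, raster: Raster) -> None:
    """Write a single-band georeferenced TIFF."""
    g = raster.grid
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell, g.cell, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x0, g.y_top, 0.0), True),
    ]
    if raster.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(raster.nodata), True))
    description = json.dumps({"crs": raster.crs})
    tifffile.imwrite(
        str(path), raster.values, extratags=extratags, description=description
    )


def read_geotiff(path) -> Raster:
    """Read a single-band georeferenced TIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        x0, y_top = float(tie[3]), float(tie[4])
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells unsupported")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            nodata = float(raw) if "." in str(raw) else int(raw)
        crs = None
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                crs = json.loads(desc.value).get("crs")
            except (json.JSONDecodeError, AttributeError):
                crs = None
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    grid = GridSpec(
        x0=x0, y_top=y_top, cell=float(sx), nrows=values.shape[0], ncols=values.shape[1]
    )
    return Raster(values=values, grid=grid, crs=crs, nodata=nodata)
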