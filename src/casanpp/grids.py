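"""Georeferenced raster grids: containers, GeoTIFF I/O, alignment, compositing.

The pipeline's universal currency is the :class:`RasterGrid` — a single-band
2D field with an axis-aligned affine georeference and an explicit nodata
sentinel.  Row 0 is the northernmost row, cell (0, 0) sits in the upper-left
corner, and coordinates refer to cell centers.

GeoTIFF files are read and written through :mod:`tifffile` using the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA and
GeoAsciiParams for the CRS label).  Only single-band, axis-aligned rasters are
supported — reprojection between datum families is out of scope.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import ndimage
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


class GridError(ValueError):
    """Raised for malformed grids or incompatible grid combinations."""


class AlignmentError(GridError):
    """Raised when an operation requires aligned grids but gets misaligned ones."""


class GridTransform(NamedTuple):
    """Axis-aligned affine map from (col, row) cell indices to projected x, y.

    ``x = c + a * col`` and ``y = f + e * row`` with ``a > 0`` and ``e < 0``
    (north-up).  ``c, f`` locate the outer corner of the upper-left cell,
    matching the GDAL convention.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def xy(self, row, col):
        """Projected coordinates of the center of cell (row, col)."""
        return (self.c + self.a * (np.asarray(col) + 0.5),
                self.f + self.e * (np.asarray(row) + 0.5))

    def rowcol(self, x, y):
        """Fractional (row, col) indices of projected point (x, y), cell-center origin."""
        return ((np.asarray(y) - self.f) / self.e - 0.5,
                (np.asarray(x) - self.c) / self.a - 0.5)

    @classmethod
    def north_up(cls, x_origin: float, y_origin: float, cell_size: float) -> "GridTransform":
        return cls(cell_size, 0.0, x_origin, 0.0, -cell_size, y_origin)


@dataclasses.dataclass
class RasterGrid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values; cells equal to ``nodata`` are missing.
    transform : GridTransform
        Affine georeference (axis-aligned, north-up).
    nodata : float
        Missing-value sentinel.
    crs_label : str
        Free-text CRS identifier; two grids only interoperate when it matches.
    """

    values: np.ndarray
    transform: GridTransform
    nodata: float = DEFAULT_NODATA
    crs_label: str = "local-albers"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GridError(f"grid must be 2D, got ndim={self.values.ndim}")
        if not isinstance(self.transform, GridTransform):
            self.transform = GridTransform(*self.transform)
        if self.transform.a <= 0 or self.transform.e >= 0:
            raise GridError("transform must be north-up with positive cell size")
        bad = ~np.isfinite(self.values)
        if bad.any():
            self.values = np.where(bad, self.nodata, self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return float(self.transform.a)

    def mask(self) -> np.ndarray:
        """Boolean mask, True where the cell holds a valid value."""
        return self.values != self.nodata

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        return np.where(self.mask(), self.values, np.nan)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.transform, other.transform)
                and self.crs_label == other.crs_label)

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """A new grid sharing this grid's georeference."""
        return RasterGrid(values, self.transform,
                          self.nodata if nodata is None else nodata, self.crs_label)

    def require_aligned(self, other: "RasterGrid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(f"{what} are not aligned (shape/transform/CRS mismatch)")


@functools.total_ordering
@dataclasses.dataclass(frozen=True)
class MonthIndex:
    """A calendar month, totally ordered with cross-year arithmetic."""

    year: int
    month: int

    def __post_init__(self):
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    def _ordinal(self) -> int:
        return self.year * 12 + (self.month - 1)

    def __lt__(self, other: "MonthIndex") -> bool:
        return self._ordinal() < other._ordinal()

    def __add__(self, n: int) -> "MonthIndex":
        o = self._ordinal() + n
        return MonthIndex(o // 12, o % 12 + 1)

    def __sub__(self, other):
        if isinstance(other, MonthIndex):
            return self._ordinal() - other._ordinal()
        return self + (-other)

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    @classmethod
    def parse(cls, text: str) -> "MonthIndex":
        y, m = text.split("-")
        return cls(int(y), int(m))


def write_grid(grid: RasterGrid, path) -> None:
    """Write a grid as a single-band GeoTIFF (float32 payload, tagged nodata)."""
    path = Path(path)
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.a, -t.e, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, grid.crs_label + "|"),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata))),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float32), extratags=extratags)


def read_grid(path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_grid` (or compatible)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise GridError(f"multi-band rasters are unsupported: {path}")
            page = tif.pages[0]
            values = page.asarray()
            if values.ndim != 2:
                raise GridError(f"expected a single-band 2D raster: {path}")
            tags = page.tags
            try:
                sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
                tie = tags[_TAG_MODEL_TIEPOINT].value
            except KeyError as exc:
                raise GridError(f"missing georeferencing tags in {path}") from exc
            transform = GridTransform(float(sx), 0.0, float(tie[3]),
                                      0.0, -float(sy), float(tie[4]))
            crs_label = "local-albers"
            if _TAG_GEO_ASCII_PARAMS in tags:
                crs_label = str(tags[_TAG_GEO_ASCII_PARAMS].value).rstrip("|\x00")
            nodata = DEFAULT_NODATA
            if _TAG_GDAL_NODATA in tags:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
    except tifffile.TiffFileError as exc:
        raise IOError(f"unreadable raster file: {path}") from exc
    return RasterGrid(np.asarray(values, dtype=np.float64), transform, nodata, crs_label)


def align(grid: RasterGrid, template: RasterGrid, method: str = "bilinear") -> RasterGrid:
    """Resample ``grid`` onto ``template``'s georeference.

    ``nearest`` is for categorical layers; ``bilinear`` for continuous fields.
    Nodata is never interpolated into valid output cells: any bilinear stencil
    touching nodata falls back to the nearest valid source cell, and cells
    outside the source extent come out nodata.
    """
    if grid.crs_label != template.crs_label:
        raise AlignmentError(
            f"CRS mismatch: {grid.crs_label!r} vs {template.crs_label!r}")
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if grid.aligned_with(template):
        return grid.like(grid.values.copy())

    rows, cols = np.indices(template.shape)
    x, y = template.transform.xy(rows, cols)
    src_r, src_c = grid.transform.rowcol(x, y)
    coords = np.stack([src_r, src_c])

    inside = ((src_r > -0.5) & (src_r < grid.shape[0] - 0.5)
              & (src_c > -0.5) & (src_c < grid.shape[1] - 0.5))

    near = ndimage.map_coordinates(grid.values, coords, order=0, mode="nearest")
    if method == "nearest":
        out = near
    else:
        src = grid.masked()
        lin = ndimage.map_coordinates(src, coords, order=1, mode="nearest")
        # NaN in the stencil poisons the bilinear result; use the nearest value there
        out = np.where(np.isnan(lin), near, lin)
    out = np.where(inside, out, grid.nodata)
    out = np.where(np.isnan(out), grid.nodata, out)
    return RasterGrid(out, template.transform, grid.nodata, template.crs_label)


def composite_monthly_ndvi(first_half: RasterGrid, second_half: RasterGrid) -> RasterGrid:
    """Monthly maximum-value composite of two sub-monthly NDVI grids.

    Per cell: the maximum of the two where both are valid; the valid one where
    only one is; nodata where both are missing.
    """
    first_half.require_aligned(second_half, "NDVI composites")
    a, b = first_half.masked(), second_half.masked()
    out = np.fmax(a, b)  # fmax ignores NaN unless both are NaN
    return first_half.like(np.where(np.isnan(out), first_half.nodata, out))


def single_composite_passthrough(only: RasterGrid) -> RasterGrid:
    """Monthly composite when only one sub-monthly grid exists (logged pass-through)."""
    logger.warning("only one sub-monthly NDVI composite available; passing through")
    return only.like(only.values.copy())
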