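"""Raster exposure surfaces: NDVI compositing and area-weighted zonal means.

The central primitive is :func:`zonal_mean`, the mean of raster cell
values weighted by the exact area of each cell's intersection with a
polygon.  Exact fractional weighting (rather than cell-center membership)
matters because park sections are routinely smaller than an exposure
cell.  Per-tract park exposure is then the section-area-weighted mean of
section zonal means, which for disjoint sections equals the zonal mean
over their union.

NDVI composites follow the growing-season convention: per-scene NDVI
from the NIR and Red bands with cloudy pixels masked, scenes with >= 20%
cloud coverage discarded outright, per-pixel temporal mean over the
remaining clear observations, and water pixels removed at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "RasterField",
    "Scene",
    "SceneStack",
    "ExposureSummary",
    "ZonalResult",
    "ndvi",
    "composite_ndvi",
    "zonal_mean",
    "tract_park_exposure",
    "nonpark_exposure",
    "urban_mean",
]

#: scenes at or above this cloud-coverage fraction never enter a composite
CLOUD_COVERAGE_LIMIT = 0.20


@dataclass
class RasterField:
    """A single-variable north-up grid.

    ``values`` is a (nrows, ncols) float array with NaN marking nodata;
    row 0 is the northernmost row.  The geotransform is the top-left
    origin ``(x0, y1)`` plus a square ``cell`` size, in the same planar
    km frame as the vector geometries.
    """

    values: np.ndarray
    x0: float
    y1: float
    cell: float
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the grid footprint."""
        return (
            self.x0,
            self.y1 - self.nrows * self.cell,
            self.x0 + self.ncols * self.cell,
            self.y1,
        )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "RasterField":
        return RasterField(
            self.values.copy(), self.x0, self.y1, self.cell, self.variable, self.units
        )

    def cell_box(self, row: int, col: int) -> BaseGeometry:
        x = self.x0 + col * self.cell
        y = self.y1 - (row + 1) * self.cell
        return shapely.box(x, y, x + self.cell, y + self.cell)


@dataclass
class Scene:
    """One acquisition: two reflectance bands plus a per-pixel cloud flag."""

    nir: np.ndarray
    red: np.ndarray
    cloud: np.ndarray  # bool; True = cloudy pixel

    def __post_init__(self) -> None:
        self.nir = np.asarray(self.nir, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.cloud = np.asarray(self.cloud, dtype=bool)
        if not (self.nir.shape == self.red.shape == self.cloud.shape):
            raise ValueError("scene bands and cloud mask must be congruent")

    @property
    def cloud_coverage(self) -> float:
        return float(self.cloud.mean())


@dataclass
class SceneStack:
    """An ordered stack of congruent scenes sharing one geotransform."""

    scenes: list[Scene]
    water_mask: np.ndarray  # bool; True = water pixel
    x0: float
    y1: float
    cell: float

    def __post_init__(self) -> None:
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        for s in self.scenes:
            if s.nir.shape != self.water_mask.shape:
                raise ValueError("all scene grids must match the water mask shape")


@dataclass
class ExposureSummary:
    tract_id: str
    variable: str
    park_mean: float            # NaN when the tract has no park sections
    nonpark_mean: float
    urban_mean: float
    weight_km2: float           # total section area entering park_mean
    valid_fraction: float = 1.0


@dataclass
class ZonalResult:
    """Outcome of one zonal aggregation.

    ``mean`` is NaN when no valid (non-nodata) cell overlaps the polygon.
    ``valid_fraction`` is the share of the overlap weight that fell on
    valid cells; aggregates dominated by nodata can be flagged on it.
    """

    mean: float
    valid_weight: float
    total_weight: float

    @property
    def valid_fraction(self) -> float:
        if self.total_weight == 0:
            return 0.0
        return self.valid_weight / self.total_weight

    @property
    def defined(self) -> bool:
        return self.valid_weight > 0


def ndvi(nir, red):
    """Normalized difference vegetation index (NIR - Red)/(NIR + Red).

    Accepts scalars or arrays; pixels with NIR + Red == 0 map to NaN.
    Reflectances must be non-negative, so the result lies in [-1, 1].
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def composite_ndvi(stack: SceneStack, coverage_limit: float = CLOUD_COVERAGE_LIMIT) -> RasterField:
    """Growing-season NDVI composite from a scene stack.

    Scenes with cloud coverage >= ``coverage_limit`` are discarded.  For
    each retained scene, NDVI is computed per pixel with cloudy pixels
    masked; the composite is the per-pixel mean over clear observations.
    Water pixels and pixels with zero clear observations become nodata.

    Raises ``ValueError`` if every scene is discarded.
    """
    if not stack.scenes:
        raise ValueError("no usable scenes: stack is empty")
    kept = [s for s in stack.scenes if s.cloud_coverage < coverage_limit]
    if not kept:
        raise ValueError(
            f"no usable scenes: all {len(stack.scenes)} scenes have cloud "
            f"coverage >= {coverage_limit:.0%}"
        )
    acc = np.zeros(stack.water_mask.shape, dtype=float)
    n_clear = np.zeros(stack.water_mask.shape, dtype=int)
    for scene in kept:
        v = ndvi(scene.nir, scene.red)
        clear = ~scene.cloud & ~np.isnan(v)
        acc[clear] += v[clear]
        n_clear[clear] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_clear > 0, acc / np.maximum(n_clear, 1), np.nan)
    out[stack.water_mask] = np.nan
    return RasterField(out, stack.x0, stack.y1, stack.cell, variable="ndvi")


def _cell_weights(raster: RasterField, polygon: BaseGeometry):
    """Exact cell-overlap areas for the cells under a polygon's bbox.

    Returns (flat cell values, flat intersection areas); both length 0
    when the polygon misses the grid.
    """
    minx, miny, maxx, maxy = polygon.bounds
    c = raster.cell
    j0 = max(int(math.floor((minx - raster.x0) / c)), 0)
    j1 = min(int(math.ceil((maxx - raster.x0) / c)), raster.ncols)
    i0 = max(int(math.floor((raster.y1 - maxy) / c)), 0)
    i1 = min(int(math.ceil((raster.y1 - miny) / c)), raster.nrows)
    if j0 >= j1 or i0 >= i1:
        return np.empty(0), np.empty(0)
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    xlo = raster.x0 + jj * c
    yhi = raster.y1 - ii * c
    boxes = shapely.box(xlo.ravel(), (yhi - c).ravel(), (xlo + c).ravel(), yhi.ravel())
    areas = shapely.area(shapely.intersection(boxes, polygon))
    vals = raster.values[i0:i1, j0:j1].ravel()
    keep = areas > 0
    return vals[keep], areas[keep]


def zonal_mean(raster: RasterField, polygon: BaseGeometry) -> ZonalResult:
    """Area-weighted mean of raster values over a polygon.

    Each overlapped cell contributes its value weighted by the exact
    area of cell-polygon intersection.  Nodata cells are excluded from
    both numerator and denominator; when no valid cell is overlapped the
    mean is NaN (undefined marker).
    """
    if polygon.is_empty:
        return ZonalResult(float("nan"), 0.0, 0.0)
    vals, w = _cell_weights(raster, polygon)
    if len(w) == 0:
        return ZonalResult(float("nan"), 0.0, 0.0)
    total_w = float(w.sum())
    valid = ~np.isnan(vals)
    valid_w = float(w[valid].sum())
    if valid_w == 0:
        return ZonalResult(float("nan"), 0.0, total_w)
    mean = float(np.dot(vals[valid], w[valid]) / valid_w)
    return ZonalResult(mean, valid_w, total_w)


def tract_park_exposure(sections: Sequence, raster: RasterField) -> ZonalResult:
    """Section-area-weighted mean exposure over a tract's park sections.

    ``sections`` carry ``geometry`` and ``area`` attributes (ParkSection).
    Sections whose zonal mean is undefined are excluded together with
    their weight.  Undefined (NaN mean) when the tract has no sections
    or no section overlaps valid cells.
    """
    num = 0.0
    valid_w = 0.0
    total_w = 0.0
    for s in sections:
        z = zonal_mean(raster, s.geometry)
        total_w += s.area
        if z.defined:
            num += s.area * z.mean
            valid_w += s.area
    if valid_w == 0:
        return ZonalResult(float("nan"), 0.0, total_w)
    return ZonalResult(num / valid_w, valid_w, total_w)


def nonpark_exposure(tract_geometry: BaseGeometry, sections: Sequence,
                     raster: RasterField) -> ZonalResult:
    """Zonal mean over the tract minus the union of its park sections.

    Undefined when parks cover the whole tract.
    """
    if sections:
        park_union = shapely.union_all([s.geometry for s in sections])
        remainder = tract_geometry.difference(park_union)
    else:
        remainder = tract_geometry
    return zonal_mean(raster, remainder)


def urban_mean(raster: RasterField, urban_extent: BaseGeometry) -> ZonalResult:
    """Area-weighted mean over the full urban extent, land cells only.

    Water/nodata cells are excluded by the zonal nodata rule; this is the
    reported definition of the "urban area mean" used in disparity
    outputs.
    """
    return zonal_mean(raster, urban_extent)
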