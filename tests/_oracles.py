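"""Independent oracles used by the acceptance-style property tests.

These deliberately avoid the package's own code paths: exhaustive
enumeration for cutpoints, jittered fine-grid integration for zonal
means, and scipy's reference Welch test.
"""

import numpy as np
import shapely


def exhaustive_cutpoints(counts, target):
    """Search all contiguous prefixes/suffixes; ties keep the larger set."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    n = len(counts)
    best_low, err_low = None, np.inf
    for k in range(1, n + 1):
        e = abs(counts[:k].sum() / total - target)
        if e < err_low - 1e-12 or abs(e - err_low) <= 1e-12:
            best_low, err_low = tuple(range(k)), min(e, err_low)
    best_high, err_high = None, np.inf
    for k in range(1, n - len(best_low) + 1):  # disjoint from the low set
        e = abs(counts[n - k:].sum() / total - target)
        if e < err_high - 1e-12 or abs(e - err_high) <= 1e-12:
            best_high, err_high = tuple(range(n - k, n)), min(e, err_high)
    return best_low, best_high


def fine_grid_zonal(raster, polygon, sub=150, rng=None):
    """Area-weighted mean by jittered fine-grid integration over the bbox."""
    minx, miny, maxx, maxy = polygon.bounds
    h = raster.cell / sub
    xs = np.arange(minx + h / 2, maxx, h)
    ys = np.arange(miny + h / 2, maxy, h)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    if rng is not None:
        gx = gx + rng.uniform(-h / 2, h / 2, gx.shape)
        gy = gy + rng.uniform(-h / 2, h / 2, gy.shape)
    shapely.prepare(polygon)
    inside = shapely.contains_xy(polygon, gx, gy)
    gx, gy = gx[inside], gy[inside]
    on = ((gx >= raster.x0) & (gx <= raster.x0 + raster.ncols * raster.cell)
          & (gy <= raster.y1) & (gy >= raster.y1 - raster.nrows * raster.cell))
    gx, gy = gx[on], gy[on]
    cols = np.clip(((gx - raster.x0) / raster.cell).astype(int), 0, raster.ncols - 1)
    rows = np.clip(((raster.y1 - gy) / raster.cell).astype(int), 0, raster.nrows - 1)
    v = raster.values[rows, cols]
    v = v[~np.isnan(v)]
    return v.mean()


def cell_enumeration_zonal(raster, polygon):
    """Exact oracle for grid-aligned rectangles: enumerate whole cells."""
    minx, miny, maxx, maxy = polygon.bounds
    c = raster.cell
    j0 = int(round((minx - raster.x0) / c))
    j1 = int(round((maxx - raster.x0) / c))
    i0 = int(round((raster.y1 - maxy) / c))
    i1 = int(round((raster.y1 - miny) / c))
    block = raster.values[i0:i1, j0:j1]
    return float(np.nanmean(block))
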