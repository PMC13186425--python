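"""NDVI math, scene compositing, and area-weighted zonal statistics."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, Polygon

from parkequity.exposure import (RasterField, Scene, SceneStack, composite_ndvi,
                                 ndvi, nonpark_exposure, tract_park_exposure,
                                 urban_mean, zonal_mean)
from parkequity.parkgeom import ParkSection

from conftest import constant_raster


class TestNdvi:
    @pytest.mark.parametrize(
        "nir,red,expected",
        [(0.4, 0.4, 0.0), (0.8, 0.0, 1.0), (0.0, 0.8, -1.0), (0.6, 0.2, 0.5)],
    )
    def test_closed_form(self, nir, red, expected):
        assert ndvi(nir, red) == pytest.approx(expected)

    def test_zero_sum_is_nodata(self):
        assert math.isnan(ndvi(0.0, 0.0))

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            ndvi(-0.1, 0.5)

    def test_array_input_bounded(self, rng):
        nir = rng.uniform(0, 1, 100)
        red = rng.uniform(0, 1, 100)
        v = ndvi(nir, red)
        assert np.all(np.abs(v[~np.isnan(v)]) <= 1.0)


def stack_from_truth(truth, n_scenes=3, cloud=None, water=None, cell=1.0):
    """Scenes whose clear pixels encode `truth` exactly (band sum 0.5)."""
    truth = np.asarray(truth, dtype=float)
    nir = 0.25 * (1 + truth)
    red = 0.25 * (1 - truth)
    scenes = []
    for k in range(n_scenes):
        c = np.zeros(truth.shape, bool) if cloud is None else cloud[k]
        scenes.append(Scene(np.where(c, 0.7, nir), np.where(c, 0.7, red), c))
    w = np.zeros(truth.shape, bool) if water is None else water
    return SceneStack(scenes, w, 0.0, truth.shape[0] * cell, cell)


class TestCompositeNdvi:
    def test_cloud_free_stack_recovers_truth_exactly(self, rng):
        truth = rng.uniform(-1, 1, (6, 6))
        out = composite_ndvi(stack_from_truth(truth))
        np.testing.assert_allclose(out.values, truth, rtol=0, atol=1e-15)

    def test_scene_at_20pct_coverage_excluded(self):
        truth = np.full((5, 4), 0.5)
        bad = np.zeros((5, 4), bool)
        bad.ravel()[:4] = True  # exactly 20% of 20 pixels: must be dropped
        clouds = [np.zeros((5, 4), bool), bad]
        stack = stack_from_truth(truth, n_scenes=2, cloud=clouds)
        # corrupt the bad scene's clear pixels: if it entered, the mean would move
        stack.scenes[1].nir[:] = 0.9
        stack.scenes[1].red[:] = 0.1
        out = composite_ndvi(stack)
        np.testing.assert_allclose(out.values, truth)

    def test_per_pixel_mean_of_clear_observations(self):
        # pixel clear in scenes with NDVI 0.2 and 0.6, cloudy in a third
        truths = [np.full((1, 1), 0.2), np.full((1, 1), 0.6), np.full((1, 1), 0.9)]
        scenes = []
        for t, cloudy in zip(truths, (False, False, True)):
            c = np.full((1, 1), cloudy)
            nir = np.where(c, 0.7, 0.25 * (1 + t))
            red = np.where(c, 0.7, 0.25 * (1 - t))
            scenes.append(Scene(nir, red, c))
        stack = SceneStack(scenes, np.zeros((1, 1), bool), 0.0, 1.0, 1.0)
        out = composite_ndvi(stack)
        assert out.values[0, 0] == pytest.approx(0.4)

    def test_water_pixels_masked_last(self):
        truth = np.full((2, 2), 0.5)
        water = np.array([[True, False], [False, False]])
        out = composite_ndvi(stack_from_truth(truth, water=water))
        assert math.isnan(out.values[0, 0])
        assert out.values[1, 1] == pytest.approx(0.5)

    def test_all_scenes_cloudy_errors(self):
        truth = np.zeros((2, 2))
        clouds = [np.ones((2, 2), bool)] * 2
        with pytest.raises(ValueError, match="no usable scenes"):
            composite_ndvi(stack_from_truth(truth, n_scenes=2, cloud=clouds))

    def test_fully_cloudy_scene_never_changes_composite(self, rng):
        truth = rng.uniform(-0.5, 0.9, (4, 4))
        base = stack_from_truth(truth, n_scenes=2)
        with_extra = stack_from_truth(truth, n_scenes=2)
        with_extra.scenes.append(
            Scene(np.full((4, 4), 0.9), np.full((4, 4), 0.1), np.ones((4, 4), bool))
        )
        np.testing.assert_array_equal(
            composite_ndvi(base).values, composite_ndvi(with_extra).values
        )

    def test_output_bounded(self, rng):
        truth = rng.uniform(-1, 1, (8, 8))
        clouds = [rng.uniform(size=(8, 8)) < 0.15 for _ in range(4)]
        out = composite_ndvi(stack_from_truth(truth, n_scenes=4, cloud=clouds)).values
        ok = ~np.isnan(out)
        assert np.all(out[ok] >= -1) and np.all(out[ok] <= 1)


def mc_zonal_oracle(raster, polygon, rng, n=200_000):
    """Monte-Carlo area-weighted mean: uniform points in the polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    inside = shapely.contains_xy(polygon, xs, ys)
    xs, ys = xs[inside], ys[inside]
    cols = np.clip(((xs - raster.x0) / raster.cell).astype(int), 0, raster.ncols - 1)
    rows = np.clip(((raster.y1 - ys) / raster.cell).astype(int), 0, raster.nrows - 1)
    on_grid = (xs >= raster.x0) & (xs <= raster.x0 + raster.ncols * raster.cell) \
        & (ys <= raster.y1) & (ys >= raster.y1 - raster.nrows * raster.cell)
    vals = raster.values[rows[on_grid], cols[on_grid]]
    vals = vals[~np.isnan(vals)]
    return vals.mean()


class TestZonalMean:
    def test_constant_raster_returns_constant(self):
        r = constant_raster(7.5)
        poly = Polygon([(0.3, 0.2), (3.1, 0.7), (1.5, 3.4)])
        assert zonal_mean(r, poly).mean == pytest.approx(7.5)

    def test_two_equal_cells(self):
        r = RasterField(np.array([[2.0, 4.0]]), 0.0, 1.0, 1.0)
        assert zonal_mean(r, shapely.box(0, 0, 2, 1)).mean == pytest.approx(3.0)

    def test_fractional_cell_weighting(self):
        # cell A (value 2) fully covered, cell B (value 4) half covered
        r = RasterField(np.array([[2.0, 4.0]]), 0.0, 1.0, 1.0)
        poly = shapely.box(0, 0, 1.5, 1)
        assert zonal_mean(r, poly).mean == pytest.approx(8.0 / 3.0)

    def test_nodata_excluded_from_both_sides(self):
        r = RasterField(np.array([[2.0, np.nan]]), 0.0, 1.0, 1.0)
        z = zonal_mean(r, shapely.box(0, 0, 2, 1))
        assert z.mean == pytest.approx(2.0)
        assert z.valid_fraction == pytest.approx(0.5)

    def test_zero_overlap_is_undefined(self):
        z = zonal_mean(constant_raster(1.0), shapely.box(10, 10, 11, 11))
        assert not z.defined and math.isnan(z.mean)

    def test_bounded_by_overlapped_cells(self, rng):
        r = RasterField(rng.normal(size=(5, 5)), 0.0, 5.0, 1.0)
        poly = Point(2.5, 2.5).buffer(1.7)
        z = zonal_mean(r, poly)
        assert r.values.min() <= z.mean <= r.values.max()

    def test_invariant_under_retriangulation(self, rng):
        r = RasterField(rng.normal(size=(4, 4)), 0.0, 4.0, 1.0)
        poly = Polygon([(0.2, 0.3), (3.7, 0.5), (3.1, 3.6), (0.9, 2.8)])
        tris = shapely.delaunay_triangles(poly)
        tris = [t.intersection(poly) for t in tris.geoms]
        num = den = 0.0
        for t in tris:
            z = zonal_mean(r, t)
            if z.defined:
                num += z.mean * z.valid_weight
                den += z.valid_weight
        assert num / den == pytest.approx(zonal_mean(r, poly).mean, rel=1e-9)

    def test_matches_monte_carlo_oracle(self, rng):
        for _ in range(5):
            r = RasterField(rng.uniform(10, 20, size=(6, 6)), 0.0, 6.0, 1.0)
            center = rng.uniform(1.5, 4.5, 2)
            poly = Point(*center).buffer(rng.uniform(0.8, 1.4), quad_segs=64)
            z = zonal_mean(r, poly)
            mc = mc_zonal_oracle(r, poly, rng)
            assert z.mean == pytest.approx(mc, rel=2e-3)


def section(geom, pid="p", tid="t"):
    return ParkSection(pid, tid, geom)


class TestTractParkExposure:
    def test_single_section_equals_its_zonal_mean(self, rng):
        r = RasterField(rng.normal(size=(3, 3)), 0.0, 3.0, 1.0)
        s = section(shapely.box(0.2, 0.2, 2.8, 2.8))
        assert tract_park_exposure([s], r).mean == pytest.approx(
            zonal_mean(r, s.geometry).mean
        )

    def test_area_weighted_combination(self):
        # areas 1 and 3 with zonal means 10 and 20 -> 17.5
        r = RasterField(np.array([[10.0, 20.0]]), 0.0, 2.0, 2.0)
        s1 = section(shapely.box(0.5, 0.5, 1.5, 1.5))          # 1 km^2 in cell 1
        s2 = section(shapely.box(2.0, 0.0, 3.5, 2.0))          # 3 km^2 in cell 2
        assert tract_park_exposure([s1, s2], r).mean == pytest.approx(17.5)

    def test_no_sections_is_undefined(self):
        z = tract_park_exposure([], constant_raster(1.0))
        assert not z.defined

    def test_equals_union_zonal_for_disjoint_sections(self, rng):
        r = RasterField(rng.uniform(0, 5, size=(4, 4)), 0.0, 4.0, 1.0)
        s1 = section(shapely.box(0.3, 0.3, 1.7, 1.2))
        s2 = section(shapely.box(2.2, 2.1, 3.8, 3.4))
        combined = tract_park_exposure([s1, s2], r).mean
        union = zonal_mean(r, shapely.union_all([s1.geometry, s2.geometry])).mean
        assert combined == pytest.approx(union, rel=1e-6)


class TestNonParkAndUrban:
    def test_no_parks_equals_whole_tract(self, rng, unit_tract):
        r = RasterField(rng.normal(size=(2, 2)), 0.0, 1.0, 0.5)
        assert nonpark_exposure(unit_tract.geometry, [], r).mean == pytest.approx(
            zonal_mean(r, unit_tract.geometry).mean
        )

    def test_constant_raster_park_equals_nonpark(self, unit_tract):
        r = constant_raster(3.3, n=2, cell=0.5)
        s = section(shapely.box(0, 0, 0.5, 0.5))
        assert nonpark_exposure(unit_tract.geometry, [s], r).mean == pytest.approx(3.3)
        assert tract_park_exposure([s], r).mean == pytest.approx(3.3)

    def test_half_tract_park_complement_by_enumeration(self, unit_tract):
        r = RasterField(np.array([[1.0, 5.0]]), 0.0, 1.0, 0.5)
        s = section(shapely.box(0, 0, 0.5, 1))  # covers the value-1 cell
        assert nonpark_exposure(unit_tract.geometry, [s], r).mean == pytest.approx(5.0)

    def test_full_cover_is_undefined(self, unit_tract):
        s = section(shapely.box(0, 0, 1, 1))
        z = nonpark_exposure(unit_tract.geometry, [s], constant_raster(1.0))
        assert not z.defined

    def test_urban_mean_enumeration(self):
        r = RasterField(np.array([[1.0, 3.0]]), 0.0, 1.0, 1.0)
        assert urban_mean(r, shapely.box(0, 0, 2, 1)).mean == pytest.approx(2.0)

    def test_mass_balance(self, unit_tract):
        s = section(shapely.box(0.2, 0.2, 0.7, 0.9))
        remainder = unit_tract.geometry.difference(s.geometry)
        assert s.geometry.area + remainder.area == pytest.approx(
            unit_tract.area, rel=1e-9
        )
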