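"""Synthetic-city generator: determinism, planted structure, round-trips."""

import dataclasses

import numpy as np
import pytest
import shapely
from scipy import stats

from parkequity.config import CityConfig, ExposureParams
from parkequity.exposure import composite_ndvi
from parkequity.privilege import assign_quartiles, compute_ice_table, select_income_cutpoints
from parkequity.synthcity import generate_city, generate_scene_stack, read_city, write_city

from conftest import small_city_config


class TestGenerateCity:
    def test_determinism_same_seed(self):
        cfg = small_city_config(seed=7)
        a = generate_city(cfg)
        b = generate_city(small_city_config(seed=7))
        assert all(x.geometry.equals(y.geometry) for x, y in zip(a.tracts, b.tracts))
        assert all(x.geometry.equals(y.geometry) for x, y in zip(a.parks, b.parks))
        for var in a.rasters:
            np.testing.assert_array_equal(a.rasters[var].values, b.rasters[var].values)
        for da, db in zip(a.demographics, b.demographics):
            np.testing.assert_array_equal(da.bracket_counts_all, db.bracket_counts_all)
            np.testing.assert_array_equal(da.bracket_counts_black, db.bracket_counts_black)

    def test_different_seeds_differ(self):
        a = generate_city(small_city_config(seed=1))
        b = generate_city(small_city_config(seed=2))
        assert not np.array_equal(a.rasters["no2"].values, b.rasters["no2"].values)

    def test_tracts_tile_the_urban_rectangle(self):
        city = generate_city(small_city_config())
        total = sum(t.area for t in city.tracts)
        assert total == pytest.approx(city.extent.area, rel=1e-9)
        union = shapely.union_all([t.geometry for t in city.tracts])
        assert union.equals(city.extent)

    def test_parks_intersect_the_extent(self):
        city = generate_city(small_city_config(n_parks=20, seed=3))
        assert len(city.parks) == 20
        assert all(p.geometry.intersects(city.extent) for p in city.parks)

    def test_noise_free_raster_is_exact_affine_of_latent(self):
        cfg = small_city_config(
            exposure_params={"no2": ExposureParams(10.0, -5.0, 0.0, "ppb")},
            raster_resolution=0.5,
        )
        city = generate_city(cfg)
        latent = {t.tract_id: t.latent for t in city.tracts}
        r = city.rasters["no2"]
        for t in city.tracts:
            minx, miny, maxx, maxy = t.geometry.bounds
            j0, j1 = int(minx / r.cell), int(maxx / r.cell)
            i0 = int((r.y1 - maxy) / r.cell)
            i1 = int((r.y1 - miny) / r.cell)
            block = r.values[i0:i1, j0:j1]
            np.testing.assert_allclose(block, 10.0 - 5.0 * latent[t.tract_id],
                                       rtol=0, atol=1e-12)

    def test_degenerate_tract_size_rejected(self):
        with pytest.raises(ValueError):
            CityConfig(tract_size=0.0)

    def test_demographics_consistent_with_latent(self):
        """Higher privilege: more high-income white householders, fewer
        low-income Black householders."""
        city = generate_city(small_city_config(demographics_mode="expected"))
        latent = {t.tract_id: t.latent for t in city.tracts}
        lo = min(city.demographics, key=lambda d: latent[d.tract_id])
        hi = max(city.demographics, key=lambda d: latent[d.tract_id])
        k = len(lo.bracket_counts_all)
        assert hi.bracket_counts_white_nh[k // 2:].sum() > lo.bracket_counts_white_nh[k // 2:].sum()
        assert hi.bracket_counts_black[: k // 2].sum() < lo.bracket_counts_black[: k // 2].sum()

    def test_ice_rank_correlates_with_latent(self):
        city = generate_city(small_city_config(n_tracts_x=10, n_tracts_y=10,
                                               demographics_mode="expected"))
        cp = select_income_cutpoints(city.demographics, 0.20)
        vals = compute_ice_table(city.demographics, cp, "combined")
        latent = city.latent_by_tract()
        rho = stats.spearmanr([latent[v.tract_id] for v in vals],
                              [v.ice for v in vals]).statistic
        assert rho > 0.9

    def test_ice_no2_correlation_negative_across_seeds(self):
        """Planted negative slope shows up as a negative ICE-NO2 correlation."""
        neg = 0
        n_seeds = 10
        for seed in range(n_seeds):
            city = generate_city(small_city_config(seed=seed))
            cp = select_income_cutpoints(city.demographics, 0.20)
            vals = compute_ice_table(city.demographics, cp, "combined")
            r = city.rasters["no2"]
            means = {}
            cells_per_tract = int(round(city.config.tract_size / r.cell))
            for i, t in enumerate(city.tracts):
                iy, ix = divmod(i, city.config.n_tracts_x)
                i0 = (city.config.n_tracts_y - 1 - iy) * cells_per_tract
                j0 = ix * cells_per_tract
                means[t.tract_id] = r.values[i0:i0 + cells_per_tract,
                                             j0:j0 + cells_per_tract].mean()
            rho = stats.pearsonr([v.ice for v in vals],
                                 [means[v.tract_id] for v in vals]).statistic
            neg += rho < 0
        assert neg == n_seeds


class TestSceneStack:
    def test_cloud_free_composite_recovers_truth(self):
        cfg = small_city_config(cloud_scene_fraction=0.0, cloud_pixel_fraction=0.0,
                                water_fraction=0.0)
        city = generate_city(cfg)
        comp = composite_ndvi(city.scenes)
        np.testing.assert_allclose(comp.values, city.truth_ndvi.values,
                                   rtol=0, atol=1e-12)

    def test_clear_scene_pixels_encode_truth(self):
        city = generate_city(small_city_config())
        s = city.scenes.scenes[-1]
        clear = ~s.cloud
        v = (s.nir - s.red) / (s.nir + s.red)
        np.testing.assert_allclose(v[clear], city.truth_ndvi.values[clear],
                                   rtol=0, atol=1e-12)

    def test_forced_bad_scene_count(self):
        cfg = small_city_config(n_scenes=10, cloud_scene_fraction=0.3,
                                cloud_pixel_fraction=0.05, n_tracts_x=10,
                                n_tracts_y=10, raster_resolution=0.25)
        city = generate_city(cfg)
        over = sum(s.cloud_coverage >= 0.20 for s in city.scenes.scenes)
        assert over == 3

    def test_expected_clear_observations_binomial(self, rng):
        """cloud_pixel_fraction 0.3 over 10 scenes -> ~7 clear obs per pixel."""
        cfg = small_city_config(n_scenes=10, cloud_scene_fraction=0.0,
                                cloud_pixel_fraction=0.3, n_tracts_x=10,
                                n_tracts_y=10, raster_resolution=0.25, seed=5)
        city = generate_city(cfg)
        n_clear = np.sum([~s.cloud for s in city.scenes.scenes], axis=0)
        assert n_clear.mean() == pytest.approx(7.0, rel=0.02)

    def test_truth_out_of_range_rejected(self):
        from parkequity.exposure import RasterField
        bad = RasterField(np.full((2, 2), 1.5), 0.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            generate_scene_stack(bad, small_city_config())


class TestWriteReadCity:
    def test_round_trip(self, tmp_path):
        city = generate_city(small_city_config(seed=11))
        write_city(city, tmp_path / "city")
        back = read_city(tmp_path / "city")
        assert len(back.tracts) == len(city.tracts)
        for a, b in zip(city.tracts, back.tracts):
            assert a.tract_id == b.tract_id
            assert a.geometry.equals_exact(b.geometry, 1e-12)
        for a, b in zip(city.parks, back.parks):
            assert a.geometry.equals_exact(b.geometry, 1e-12)
        np.testing.assert_allclose(back.rasters["no2"].values,
                                   city.rasters["no2"].values, rtol=0, atol=0)
        for sa, sb in zip(city.scenes.scenes, back.scenes.scenes):
            np.testing.assert_allclose(sa.nir, sb.nir, rtol=0, atol=0)
            np.testing.assert_array_equal(sa.cloud, sb.cloud)
        da, db = city.demographics[3], back.demographics[3]
        np.testing.assert_array_equal(da.bracket_counts_all, db.bracket_counts_all)

    def test_empty_park_set_round_trips(self, tmp_path):
        city = generate_city(small_city_config(n_parks=0))
        write_city(city, tmp_path / "city")
        back = read_city(tmp_path / "city")
        assert back.parks == []

    def test_written_artifacts_deterministic(self, tmp_path):
        import hashlib

        def digest(d):
            h = hashlib.sha256()
            for p in sorted(d.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        for sub in ("a", "b"):
            write_city(generate_city(small_city_config(seed=4)), tmp_path / sub)
        assert digest(tmp_path / "a") == digest(tmp_path / "b")
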