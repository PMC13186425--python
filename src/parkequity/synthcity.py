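"""Synthetic urban areas with planted equity structure.

A city is a rectangular lattice of square tracts.  A linear gradient
maps tract position to a latent privilege score in [-1, 1]; everything
downstream is driven by that score:

* demographics — householder income brackets drawn from a discretized
  normal whose mean shifts with privilege; race/ethnicity split within
  each bracket shifts the same way, so the combined race+income ICE is
  monotone in the latent score in expectation;
* parks — placement probability and size multiplied by logistic
  functions of local privilege (``park_placement_bias`` 0 = unbiased);
* exposure rasters — each cell takes ``intercept + slope * latent`` of
  its containing tract plus iid Gaussian noise, so the true Q1-Q4
  contrast is known in closed form;
* NDVI — a truth raster of the same affine form (clipped to [-1, 1])
  observed through a stack of two-band scenes with planted clouds and a
  contiguous water blob.

Identical (config, seed) reproduce bit-identical cities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import shapely
from scipy.stats import norm
from shapely.geometry import Polygon

from .config import CityConfig, ExposureParams
from .exposure import RasterField, Scene, SceneStack
from .parkgeom import ParkRecord, Tract
from .privilege import DemographicTable

#: reflectance assigned to both bands of a cloud-contaminated pixel
CLOUD_REFLECTANCE = 0.7
#: minimum per-pixel cloud probability forced onto over-threshold scenes
BAD_SCENE_PIXEL_PROB = 0.35


@dataclass
class SyntheticCity:
    config: CityConfig
    tracts: list[Tract]
    demographics: list[DemographicTable]
    parks: list[ParkRecord]
    rasters: dict[str, RasterField]
    truth_ndvi: RasterField
    scenes: SceneStack
    water_mask: np.ndarray
    extent: Polygon
    truth: dict = field(default_factory=dict)

    @property
    def urban_area_id(self) -> str:
        return self.config.urban_area_id

    def latent_by_tract(self) -> dict[str, float]:
        return {t.tract_id: t.latent for t in self.tracts}


# ---------------------------------------------------------------------------
# latent privilege surface

def _latent_scores(cfg: CityConfig) -> np.ndarray:
    """Latent privilege per tract, shape (ny, nx), in [-strength, strength]."""
    theta = math.radians(cfg.gradient_direction_deg)
    ix = np.arange(cfg.n_tracts_x)
    iy = np.arange(cfg.n_tracts_y)
    cx = (ix + 0.5) * cfg.tract_size
    cy = (iy + 0.5) * cfg.tract_size
    gx, gy = np.meshgrid(cx, cy)
    proj = (gx - cfg.width / 2) * math.cos(theta) + (gy - cfg.height / 2) * math.sin(theta)
    m = np.abs(proj).max()
    if m == 0:  # single tract, or gradient orthogonal to the only axis
        return np.zeros_like(proj)
    return cfg.gradient_strength * proj / m


def _tract_index_of_points(x: np.ndarray, y: np.ndarray, cfg: CityConfig):
    ix = np.clip((x / cfg.tract_size).astype(int), 0, cfg.n_tracts_x - 1)
    iy = np.clip((y / cfg.tract_size).astype(int), 0, cfg.n_tracts_y - 1)
    return ix, iy


# ---------------------------------------------------------------------------
# demographics

def _bracket_probs(latent: float, cfg: CityConfig) -> np.ndarray:
    """Income-bracket probabilities, shifted up-bracket with privilege."""
    k = cfg.n_brackets
    cuts = norm.ppf(np.linspace(1 / k, (k - 1) / k, k - 1))
    mu = 0.8 * latent
    cdf = np.concatenate([[0.0], norm.cdf(cuts - mu), [1.0]])
    return np.diff(cdf)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _race_probs(latent: float, cfg: CityConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-bracket (p_white_nh, p_black); p_white + p_black <= 1."""
    b = np.arange(cfg.n_brackets) - (cfg.n_brackets - 1) / 2
    p_white = _sigmoid(-0.2 + 1.5 * latent + 0.25 * b)
    p_black = (1.0 - p_white) * _sigmoid(-0.5 - 1.5 * latent - 0.25 * b)
    return p_white, p_black


def _make_demographics(tract_id: str, latent: float, cfg: CityConfig,
                       rng: np.random.Generator) -> DemographicTable:
    n = cfg.households_per_tract
    probs = _bracket_probs(latent, cfg)
    p_white, p_black = _race_probs(latent, cfg)
    if cfg.demographics_mode == "expected":
        all_counts = np.round(n * probs).astype(np.int64)
        white = np.minimum(np.round(all_counts * p_white), all_counts).astype(np.int64)
        black = np.minimum(np.round(all_counts * p_black), all_counts - white).astype(np.int64)
    else:
        all_counts = rng.multinomial(n, probs)
        white = rng.binomial(all_counts, p_white)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_b_rest = np.where(p_white < 1, p_black / (1 - p_white), 0.0)
        black = rng.binomial(all_counts - white, np.clip(p_b_rest, 0, 1))
    return DemographicTable(
        tract_id=tract_id,
        urban_area_id=cfg.urban_area_id,
        bracket_counts_all=all_counts,
        bracket_counts_black=black,
        bracket_counts_white_nh=white,
        race_white_nh=int(white.sum()),
        race_black=int(black.sum()),
        race_total=int(all_counts.sum()),
    )


# ---------------------------------------------------------------------------
# parks

def _make_parks(cfg: CityConfig, latent_grid: np.ndarray,
                rng: np.random.Generator) -> list[ParkRecord]:
    parks = []
    lo, hi = cfg.park_size_range
    i = 0
    attempts = 0
    max_attempts = max(cfg.n_parks * 200, 1000)
    while len(parks) < cfg.n_parks and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(0, cfg.width)
        y = rng.uniform(0, cfg.height)
        ix, iy = _tract_index_of_points(np.array([x]), np.array([y]), cfg)
        latent = float(latent_grid[iy[0], ix[0]])
        # placement bias: accept with a logistic weight in local privilege
        # (bias 0 -> constant 0.5 acceptance, i.e. uniform placement)
        if rng.uniform() > _sigmoid(2.0 * cfg.park_placement_bias * latent):
            continue
        base = rng.uniform(lo, hi)
        size = base * 2.0 * _sigmoid(2.0 * cfg.park_placement_bias * latent)
        side = math.sqrt(size)
        geom = shapely.box(x - side / 2, y - side / 2, x + side / 2, y + side / 2)
        parks.append(ParkRecord(f"p{i:04d}", f"Park {i:04d}", geom))
        i += 1
    return parks


# ---------------------------------------------------------------------------
# rasters & scenes

def _raster_grid(cfg: CityConfig) -> tuple[int, int]:
    ncols = max(int(round(cfg.width / cfg.raster_resolution)), 1)
    nrows = max(int(round(cfg.height / cfg.raster_resolution)), 1)
    return nrows, ncols


def _cell_latents(cfg: CityConfig, latent_grid: np.ndarray) -> np.ndarray:
    nrows, ncols = _raster_grid(cfg)
    res = cfg.raster_resolution
    xs = (np.arange(ncols) + 0.5) * res
    ys = cfg.height - (np.arange(nrows) + 0.5) * res  # row 0 = top
    gx, gy = np.meshgrid(xs, ys)
    ix, iy = _tract_index_of_points(gx, gy, cfg)
    return latent_grid[iy, ix]


def _make_raster(var: str, params: ExposureParams, cell_latent: np.ndarray,
                 cfg: CityConfig, rng: np.random.Generator,
                 clip: Optional[tuple[float, float]] = None) -> RasterField:
    vals = params.intercept + params.slope_vs_privilege * cell_latent
    if params.noise_sd > 0:
        vals = vals + rng.normal(0.0, params.noise_sd, size=vals.shape)
    if clip is not None:
        vals = np.clip(vals, *clip)
    return RasterField(vals, 0.0, cfg.height, cfg.raster_resolution,
                       variable=var, units=params.units)


def _make_water_mask(cfg: CityConfig, shape: tuple[int, int]) -> np.ndarray:
    """Contiguous blob: cells within a radius of the SW corner."""
    nrows, ncols = shape
    mask = np.zeros(shape, dtype=bool)
    target = cfg.water_fraction * nrows * ncols
    if target < 0.5:
        return mask
    r = math.sqrt(4 * target / math.pi)  # quarter-disc area = target
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    # SW corner of the grid = bottom-left = last row, first column
    d = np.hypot(jj + 0.5, (nrows - 1 - ii) + 0.5)
    mask[d <= r] = True
    return mask


def generate_scene_stack(truth_ndvi: RasterField, config: CityConfig,
                         rng: Optional[np.random.Generator] = None,
                         water_mask: Optional[np.ndarray] = None) -> SceneStack:
    """Observe a truth NDVI raster through a stack of noisy-sky scenes.

    Clear pixels carry bands with (NIR-Red)/(NIR+Red) equal to the truth
    value exactly; cloud-flagged pixels get contaminated bands.  A
    deterministic count ``round(cloud_scene_fraction * n_scenes)`` of
    scenes is forced over the 20% coverage threshold so composites must
    discard them.
    """
    t = truth_ndvi.values
    if np.nanmin(t) < -1 or np.nanmax(t) > 1:
        raise ValueError("truth NDVI values must lie in [-1, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if water_mask is None:
        water_mask = np.zeros(t.shape, dtype=bool)
    total = 0.5  # constant band sum; any positive value reproduces the ratio
    nir_clear = total * (1 + t) / 2
    red_clear = total * (1 - t) / 2
    n_bad = int(round(config.cloud_scene_fraction * config.n_scenes))
    scenes = []
    for k in range(config.n_scenes):
        p = max(BAD_SCENE_PIXEL_PROB, config.cloud_pixel_fraction) if k < n_bad \
            else config.cloud_pixel_fraction
        cloud = rng.uniform(size=t.shape) < p
        nir = np.where(cloud, CLOUD_REFLECTANCE, nir_clear)
        red = np.where(cloud, CLOUD_REFLECTANCE, red_clear)
        scenes.append(Scene(nir, red, cloud))
    return SceneStack(scenes, water_mask, truth_ndvi.x0, truth_ndvi.y1, truth_ndvi.cell)


# ---------------------------------------------------------------------------
# city assembly

def generate_city(config: CityConfig) -> SyntheticCity:
    """Generate a complete synthetic urban area from a config.

    Deterministic: identical (config, seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    latent_grid = _latent_scores(config)

    tracts, demographics = [], []
    for iy in range(config.n_tracts_y):
        for ix in range(config.n_tracts_x):
            tid = f"t{iy:03d}{ix:03d}"
            geom = shapely.box(ix * config.tract_size, iy * config.tract_size,
                               (ix + 1) * config.tract_size, (iy + 1) * config.tract_size)
            latent = float(latent_grid[iy, ix])
            tracts.append(Tract(tid, geom, config.urban_area_id, latent))
            demographics.append(_make_demographics(tid, latent, config, rng))

    parks = _make_parks(config, latent_grid, rng)

    cell_latent = _cell_latents(config, latent_grid)
    rasters = {
        var: _make_raster(var, params, cell_latent, config, rng)
        for var, params in config.exposure_params.items()
    }
    truth_ndvi = _make_raster("ndvi", config.ndvi_params, cell_latent, config,
                              rng, clip=(-1.0, 1.0))
    water_mask = _make_water_mask(config, truth_ndvi.values.shape)
    scenes = generate_scene_stack(truth_ndvi, config, rng, water_mask)

    extent = shapely.box(0.0, 0.0, config.width, config.height)
    truth = {
        "seed": config.seed,
        "latent_by_tract": {t.tract_id: t.latent for t in tracts},
        "exposure_params": {
            v: {"intercept": p.intercept, "slope_vs_privilege": p.slope_vs_privilege,
                "noise_sd": p.noise_sd, "units": p.units}
            for v, p in config.exposure_params.items()
        },
        "ndvi_params": {
            "intercept": config.ndvi_params.intercept,
            "slope_vs_privilege": config.ndvi_params.slope_vs_privilege,
            "noise_sd": config.ndvi_params.noise_sd,
        },
    }
    return SyntheticCity(config, tracts, demographics, parks, rasters,
                         truth_ndvi, scenes, water_mask, extent, truth)


def write_city(city: SyntheticCity, directory: str | Path) -> dict[str, Path]:
    """Write a city as GeoJSON + ASCII-grid rasters + CSV + JSON truth.

    Round-trips losslessly (within float formatting) through
    :func:`read_city`.  Returns the mapping of artifact name to path.
    """
    from . import io as pio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": d / "city_config.yaml",
        "tracts": d / "tracts.geojson",
        "parks": d / "parks.geojson",
        "demographics": d / "demographics.csv",
        "truth": d / "truth.json",
        "water_mask": d / "water_mask.asc",
    }
    city.config.to_yaml(paths["config"])
    pio.write_tracts_geojson(city.tracts, paths["tracts"])
    pio.write_parks_geojson(city.parks, paths["parks"])
    pio.write_demographics_csv(city.demographics, paths["demographics"])
    with open(paths["truth"], "w") as fh:
        json.dump(city.truth, fh, indent=1, sort_keys=True)
    pio.write_ascii_grid(
        RasterField(city.water_mask.astype(float), city.truth_ndvi.x0,
                    city.truth_ndvi.y1, city.truth_ndvi.cell, "water"),
        paths["water_mask"],
    )
    for var, r in city.rasters.items():
        p = d / f"raster_{var}.asc"
        pio.write_ascii_grid(r, p)
        paths[f"raster_{var}"] = p
    scenes_dir = d / "scenes"
    scenes_dir.mkdir(exist_ok=True)
    for k, s in enumerate(city.scenes.scenes):
        for band, arr in (("nir", s.nir), ("red", s.red), ("cloud", s.cloud.astype(float))):
            p = scenes_dir / f"scene{k:02d}_{band}.asc"
            pio.write_ascii_grid(
                RasterField(arr, city.scenes.x0, city.scenes.y1, city.scenes.cell, band), p
            )
            paths[f"scene{k:02d}_{band}"] = p
    return paths


def read_city(directory: str | Path) -> SyntheticCity:
    """Reconstitute a city written by :func:`write_city`."""
    from . import io as pio

    d = Path(directory)
    config = CityConfig.from_yaml(d / "city_config.yaml")
    tracts = pio.read_tracts_geojson(d / "tracts.geojson")
    parks = pio.read_parks_geojson(d / "parks.geojson")
    demographics = pio.read_demographics_csv(d / "demographics.csv")
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    water = pio.read_ascii_grid(d / "water_mask.asc")
    rasters = {}
    for var in config.exposure_params:
        rasters[var] = pio.read_ascii_grid(d / f"raster_{var}.asc", variable=var)
    scenes = []
    k = 0
    while (d / "scenes" / f"scene{k:02d}_nir.asc").exists():
        nir = pio.read_ascii_grid(d / "scenes" / f"scene{k:02d}_nir.asc")
        red = pio.read_ascii_grid(d / "scenes" / f"scene{k:02d}_red.asc")
        cloud = pio.read_ascii_grid(d / "scenes" / f"scene{k:02d}_cloud.asc")
        scenes.append(Scene(nir.values, red.values, cloud.values > 0.5))
        k += 1
    water_mask = water.values > 0.5
    stack = SceneStack(scenes, water_mask, water.x0, water.y1, water.cell)
    # truth NDVI is recomputed lazily from scene math only for synthetic
    # round-trips; the composite is the pipeline's NDVI source
    truth_ndvi = RasterField(np.full(water_mask.shape, np.nan), water.x0,
                             water.y1, water.cell, "ndvi")
    extent = shapely.box(0.0, 0.0, config.width, config.height)
    return SyntheticCity(config, tracts, demographics, parks, rasters,
                         truth_ndvi, stack, water_mask, extent, truth)
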