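"""Configuration objects for synthetic cities and pipeline runs.

Synthetic cities live in a planar, equal-area coordinate frame with km
units, so polygon area is Euclidean area.  Real-data use requires the
caller to supply geometries already projected to an equal-area CRS.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class ExposureParams:
    """Planted affine model for one exposure surface.

    Each raster cell takes ``intercept + slope_vs_privilege * latent`` of
    its containing tract, plus iid Gaussian noise with ``noise_sd``
    (all in the variable's native units).
    """

    intercept: float
    slope_vs_privilege: float
    noise_sd: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_exposure_params() -> dict[str, ExposureParams]:
    """Default planted surfaces: scales mirror typical urban disparities.

    With the default privilege gradient the Q1/Q4 latent gap is ~1.2, so
    these slopes plant Q1-Q4 park differences of roughly +1.2 ppb NO2,
    +1.0 ug/m3 PM2.5 and +1.2 degC WBGT (less privileged higher).
    """
    return {
        "no2": ExposureParams(12.0, -1.0, 1.0, "ppb"),
        "pm25": ExposureParams(8.0, -0.8, 0.8, "ug/m3"),
        "wbgt": ExposureParams(24.0, -1.0, 0.5, "degC"),
    }


@dataclass
class CityConfig:
    """Parameters of one synthetic urban area.

    The urban extent is an ``n_tracts_x x n_tracts_y`` lattice of square
    tracts of side ``tract_size`` km.  A linear privilege gradient maps
    tract position to a latent score in [-1, 1]; demographics, park
    placement and exposure rasters are all driven by that latent score.
    """

    n_tracts_x: int = 20
    n_tracts_y: int = 20
    tract_size: float = 1.0                      # km
    gradient_direction_deg: float = 45.0         # direction of increasing privilege
    gradient_strength: float = 1.0               # scales latent into [-strength, strength]
    n_parks: int = 60
    park_size_range: tuple[float, float] = (0.05, 1.2)   # km^2
    park_placement_bias: float = 0.5             # >0: more/larger parks where privileged
    exposure_params: dict[str, ExposureParams] = field(
        default_factory=default_exposure_params
    )
    ndvi_params: ExposureParams = field(
        default_factory=lambda: ExposureParams(0.35, 0.025, 0.05, "unitless")
    )
    raster_resolution: float = 0.25              # km; should divide tract_size
    n_scenes: int = 8
    cloud_scene_fraction: float = 0.25           # share of scenes pushed over 20% coverage
    cloud_pixel_fraction: float = 0.10           # per-pixel cloud probability, clear scenes
    water_fraction: float = 0.05                 # share of cells in the water blob
    n_brackets: int = 16
    households_per_tract: int = 1200
    demographics_mode: str = "sampled"           # "sampled" | "expected"
    urban_area_id: str = "synthcity"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_tracts_x < 1 or self.n_tracts_y < 1:
            raise ValueError("tract counts must be >= 1")
        if self.tract_size <= 0:
            raise ValueError("tract_size must be > 0")
        if self.n_parks < 0:
            raise ValueError("n_parks must be >= 0")
        lo, hi = self.park_size_range
        if not (0 < lo <= hi):
            raise ValueError("park_size_range must satisfy 0 < lo <= hi")
        if self.raster_resolution <= 0:
            raise ValueError("raster_resolution must be > 0")
        if self.n_scenes < 1:
            raise ValueError("n_scenes must be >= 1")
        for name in ("cloud_scene_fraction", "cloud_pixel_fraction", "water_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_brackets < 2:
            raise ValueError("n_brackets must be >= 2")
        if self.households_per_tract < 1:
            raise ValueError("households_per_tract must be >= 1")
        if self.demographics_mode not in ("sampled", "expected"):
            raise ValueError("demographics_mode must be 'sampled' or 'expected'")

    # -- geometry helpers -------------------------------------------------
    @property
    def width(self) -> float:
        return self.n_tracts_x * self.tract_size

    @property
    def height(self) -> float:
        return self.n_tracts_y * self.tract_size

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["park_size_range"] = list(self.park_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CityConfig":
        d = dict(d)
        if "exposure_params" in d:
            d["exposure_params"] = {
                k: ExposureParams(**v) if isinstance(v, dict) else v
                for k, v in d["exposure_params"].items()
            }
        if isinstance(d.get("ndvi_params"), dict):
            d["ndvi_params"] = ExposureParams(**d["ndvi_params"])
        if "park_size_range" in d:
            d["park_size_range"] = tuple(d["park_size_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CityConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synth`` (generate a city in memory) or ``inputs``
    (paths to tracts/demographics/parks/rasters/scenes on disk) must be
    set.
    """

    synth: Optional[CityConfig] = None
    inputs: Optional[dict[str, str]] = None      # keys: city_dir OR explicit paths
    variants: tuple[str, ...] = ("combined",)    # subset of combined|race|income
    target_share: float = 0.20
    cutpoint_scope: str = "pooled"               # pooled | per_urban_area
    nonpark_sensitivity: bool = True
    compute_ndvi: bool = True
    output_dir: Optional[str] = None
    write_inputs: bool = False
    seed: Optional[int] = None                   # overrides synth.seed when set

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("exactly one of synth / inputs must be given")
        if not (0 < self.target_share < 0.5):
            raise ValueError("target_share must be in (0, 0.5)")
        if self.cutpoint_scope not in ("pooled", "per_urban_area"):
            raise ValueError("cutpoint_scope must be pooled or per_urban_area")
        bad = set(self.variants) - {"combined", "race", "income"}
        if bad:
            raise ValueError(f"unknown ICE variants: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "synth" in d and d["synth"] is not None:
            d["synth"] = CityConfig.from_dict(d["synth"])
        if "variants" in d:
            d["variants"] = tuple(d["variants"])
        return cls(**d)
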