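"""End-to-end orchestration: privilege -> park geometry -> exposure -> disparity.

A run starts from either a generated synthetic city or a directory of
input files, and produces tract-level ICE/quartile assignments, park
size metrics, park and non-park exposure means, and per-variable
quartile disparity results, together with a machine-readable run log
recording every exclusion and in-force analysis decision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pio
from .config import CityConfig, RunConfig
from .disparity import DisparityResult, compare_quartiles, disparity_frame
from .exposure import (RasterField, composite_ndvi, nonpark_exposure,
                       tract_park_exposure, urban_mean, zonal_mean)
from .parkgeom import section_parks, sections_by_tract, size_metrics
from .privilege import (IceCutpoints, assign_quartiles, compute_ice_table,
                        ice_frame, select_income_cutpoints)
from .synthcity import SyntheticCity, generate_city, read_city, write_city

log = logging.getLogger(__name__)

SIZE_VARIABLES = ("percent_park", "largest_intersecting_park_area_km2")

DECISIONS_IN_FORCE = [
    "cutpoints: contiguous bracket set closest to target share; ties include the extra bracket",
    "quartiles: rank-based within urban area, ties by tract id, extras to lower quartiles",
    "undefined-ICE tracts excluded from quartiles and downstream means",
    "percent_park: overlapping park footprints unioned before division",
    "largest intersecting park: full unclipped area, boundary touches count",
    "zonal means: exact fractional cell-overlap weighting, nodata excluded",
    "NDVI: per-scene NDVI then temporal mean; scenes >= 20% cloud dropped; water masked last",
    "urban mean: land cells of the full urban extent",
    "t-test: Welch unequal-variance, two-sided; no multiple-testing correction",
    "percent difference: (Q1 - Q4) / Q4 * 100",
]


@dataclass
class PipelineResult:
    city: SyntheticCity
    cutpoints: object                     # IceCutpoints or dict by urban area
    ice: pd.DataFrame                     # tract x variant with quartiles
    sizes: pd.DataFrame                   # per-tract size metrics
    exposures: pd.DataFrame               # tract x variable park/nonpark/urban means
    results: list[DisparityResult]
    disparities: pd.DataFrame
    run_log: dict

    def result_for(self, variant: str, variable: str) -> DisparityResult:
        for r in self.results:
            if r.variant == variant and r.variable == variable:
                return r
        raise KeyError((variant, variable))


def _quartile_lookup(assignments) -> dict[str, int]:
    return {a.tract_id: a.quartile for a in assignments}


def analyze_city(city: SyntheticCity, cfg: RunConfig) -> PipelineResult:
    """Run the full analysis on an in-memory city."""
    run_log: dict = {"urban_area_id": city.urban_area_id, "exclusions": [],
                     "decisions": list(DECISIONS_IN_FORCE)}

    # --- privilege -------------------------------------------------------
    cutpoints = select_income_cutpoints(city.demographics, cfg.target_share,
                                        cfg.cutpoint_scope)
    cp = cutpoints[city.urban_area_id] if isinstance(cutpoints, dict) else cutpoints
    run_log["cutpoints"] = {
        "low_brackets": list(cp.low_brackets),
        "high_brackets": list(cp.high_brackets),
        "achieved_low_share": cp.achieved_low_share,
        "achieved_high_share": cp.achieved_high_share,
        "scope": cp.scope,
    }

    ice_values = {}
    quartiles = {}
    all_assignments = []
    for variant in cfg.variants:
        vals = compute_ice_table(city.demographics, cp, variant)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignments, excluded = assign_quartiles(vals)
        for tid in excluded:
            run_log["exclusions"].append(
                {"stage": "privilege", "variant": variant, "tract_id": tid,
                 "reason": "undefined ICE (zero denominator)"}
            )
        ice_values[variant] = vals
        quartiles[variant] = _quartile_lookup(assignments)
        all_assignments.extend(assignments)
    ice_df = ice_frame(sum(ice_values.values(), []), all_assignments)

    # --- park geometry ---------------------------------------------------
    sections = section_parks(city.parks, city.tracts)
    by_tract = sections_by_tract(sections)
    sizes = size_metrics(city.parks, city.tracts, sections)

    # --- exposure --------------------------------------------------------
    rasters = dict(city.rasters)
    if cfg.compute_ndvi and city.scenes.scenes:
        n_dropped = sum(
            1 for s in city.scenes.scenes if s.cloud_coverage >= 0.20
        )
        run_log["scenes"] = {"total": len(city.scenes.scenes), "dropped": n_dropped}
        rasters["ndvi"] = composite_ndvi(city.scenes)

    exp_rows = []
    tract_values: dict[str, dict[str, float]] = {v: {} for v in rasters}
    nonpark_values: dict[str, dict[str, float]] = {v: {} for v in rasters}
    urban_means: dict[str, float] = {}
    for var, raster in rasters.items():
        urban_means[var] = urban_mean(raster, city.extent).mean
        for t in city.tracts:
            secs = by_tract.get(t.tract_id, [])
            park = tract_park_exposure(secs, raster)
            if cfg.nonpark_sensitivity:
                nonpark = nonpark_exposure(t.geometry, secs, raster)
            else:
                nonpark = None
            tract_values[var][t.tract_id] = park.mean
            if nonpark is not None:
                nonpark_values[var][t.tract_id] = nonpark.mean
            if not secs:
                run_log["exclusions"].append(
                    {"stage": "exposure", "variable": var, "tract_id": t.tract_id,
                     "reason": "no park sections; excluded from park quartile means"}
                )
            exp_rows.append(
                {
                    "tract_id": t.tract_id,
                    "variable": var,
                    "park_mean": park.mean,
                    "nonpark_mean": nonpark.mean if nonpark is not None else np.nan,
                    "urban_mean": urban_means[var],
                    "weight_km2": park.valid_weight,
                    "valid_fraction": park.valid_fraction,
                }
            )
    exposures = pd.DataFrame(exp_rows)

    # --- disparity -------------------------------------------------------
    size_by_tract = {
        var: dict(zip(sizes["tract_id"], sizes[var])) for var in SIZE_VARIABLES
    }
    results: list[DisparityResult] = []
    n_tests = 0
    for variant in cfg.variants:
        qmap = quartiles[variant]
        tids = sorted(qmap)
        qlabels = [qmap[t] for t in tids]

        def _compare(values_by_tract, variable, umean=float("nan")):
            vals = [values_by_tract.get(t, np.nan) for t in tids]
            return compare_quartiles(vals, qlabels, city.urban_area_id,
                                     variant, variable, umean)

        for var in rasters:
            results.append(_compare(tract_values[var], var, urban_means[var]))
            n_tests += 1
            if cfg.nonpark_sensitivity:
                results.append(_compare(nonpark_values[var], f"{var}_nonpark",
                                        urban_means[var]))
                n_tests += 1
        for var in SIZE_VARIABLES:
            results.append(_compare(size_by_tract[var], var))
            n_tests += 1
    run_log["n_tests"] = n_tests
    run_log["n_tracts"] = len(city.tracts)
    run_log["n_parks"] = len(city.parks)
    run_log["n_sections"] = len(sections)

    return PipelineResult(city, cutpoints, ice_df, sizes, exposures, results,
                          disparity_frame(results), run_log)


def load_city(cfg: RunConfig) -> SyntheticCity:
    if cfg.synth is not None:
        synth = cfg.synth
        if cfg.seed is not None:
            synth = dataclasses.replace(synth, seed=cfg.seed)
        return generate_city(synth)
    inputs = cfg.inputs
    if "city_dir" in inputs:
        d = Path(inputs["city_dir"])
        for required in ("tracts.geojson", "parks.geojson", "demographics.csv"):
            if not (d / required).exists():
                raise FileNotFoundError(f"input file not found: {d / required}")
        return read_city(d)
    raise ValueError("inputs must provide 'city_dir'")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the pipeline and (when configured) write all outputs.

    Output files: ice.csv, size_metrics.csv, exposure.csv, disparity.csv
    and run_log.json under ``cfg.output_dir``; input artifacts are also
    written there when ``cfg.write_inputs`` is set.
    """
    city = load_city(cfg)
    result = analyze_city(city, cfg)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.write_inputs:
            write_city(city, out / "inputs")
        result.ice.to_csv(out / "ice.csv", index=False)
        result.sizes.to_csv(out / "size_metrics.csv", index=False)
        result.exposures.to_csv(out / "exposure.csv", index=False)
        result.disparities.to_csv(out / "disparity.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(result.run_log, fh, indent=1, sort_keys=True)
    return result
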