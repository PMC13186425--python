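"""Readers and writers for the pipeline's on-disk formats.

Vectors travel as GeoJSON feature collections (planar km coordinates,
declared in the collection metadata), rasters as ESRI ASCII grids
(plain-text, single band, NODATA tagged), and demographic tables as CSV
with per-stratum bracket columns ``all_b01..``, ``black_b01..``,
``whitenh_b01..``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .exposure import RasterField
from .parkgeom import ParkRecord, Tract
from .privilege import DemographicTable

NODATA = -9999.0


class SchemaError(ValueError):
    """A file exists but does not match the expected schema."""


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


# ---------------------------------------------------------------------------
# GeoJSON vectors

def _feature_collection(features: list[dict]) -> dict:
    return {
        "type": "FeatureCollection",
        "crs_note": "planar equal-area frame, km units",
        "features": features,
    }


def write_tracts_geojson(tracts: Sequence[Tract], path: str | Path) -> None:
    feats = []
    for t in tracts:
        props = {"tract_id": t.tract_id, "urban_area_id": t.urban_area_id}
        if t.latent is not None:
            props["latent"] = t.latent
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(t.geometry)})
    with open(path, "w") as fh:
        json.dump(_feature_collection(feats), fh)


def read_tracts_geojson(path: str | Path) -> list[Tract]:
    with open(_require(path)) as fh:
        fc = json.load(fh)
    tracts = []
    for i, f in enumerate(fc.get("features", [])):
        props = f.get("properties", {})
        if "tract_id" not in props:
            raise SchemaError(f"{path}: feature {i} lacks 'tract_id'")
        tracts.append(
            Tract(str(props["tract_id"]), shape(f["geometry"]),
                  str(props.get("urban_area_id", "")), props.get("latent"))
        )
    return tracts


def write_parks_geojson(parks: Sequence[ParkRecord], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"park_id": p.park_id, "name": p.name, "area_km2": p.area},
            "geometry": mapping(p.geometry),
        }
        for p in parks
    ]
    with open(path, "w") as fh:
        json.dump(_feature_collection(feats), fh)


def read_parks_geojson(path: str | Path) -> list[ParkRecord]:
    with open(_require(path)) as fh:
        fc = json.load(fh)
    parks = []
    for i, f in enumerate(fc.get("features", [])):
        props = f.get("properties", {})
        if "park_id" not in props:
            raise SchemaError(f"{path}: feature {i} lacks 'park_id'")
        geom = shape(f["geometry"])
        parks.append(ParkRecord(str(props["park_id"]),
                                str(props.get("name", props["park_id"])), geom))
    return parks


# ---------------------------------------------------------------------------
# ASCII-grid rasters

def write_ascii_grid(raster: RasterField, path: str | Path) -> None:
    """ESRI ASCII grid: 6 header lines, then rows north to south."""
    vals = np.where(np.isnan(raster.values), NODATA, raster.values)
    yll = raster.y1 - raster.nrows * raster.cell
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {raster.cell!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        np.savetxt(fh, vals, fmt="%.17g")


def read_ascii_grid(path: str | Path, variable: str = "") -> RasterField:
    p = _require(path)
    header: dict[str, float] = {}
    with open(p) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if k not in header:
            raise SchemaError(f"{p}: missing ASCII-grid header field {k!r}")
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise SchemaError(f"{p}: grid shape does not match header")
    y1 = header["yllcorner"] + header["nrows"] * header["cellsize"]
    return RasterField(vals, header["xllcorner"], y1, header["cellsize"], variable)


# ---------------------------------------------------------------------------
# demographics CSV

def _bracket_cols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_b{i + 1:02d}" for i in range(n)]


def write_demographics_csv(tables: Sequence[DemographicTable], path: str | Path) -> None:
    if not tables:
        raise ValueError("no demographic tables to write")
    n = len(tables[0].bracket_counts_all)
    cols = (["tract_id", "urban_area_id"]
            + _bracket_cols("all", n) + _bracket_cols("black", n)
            + _bracket_cols("whitenh", n)
            + ["race_white_nh", "race_black", "race_total"])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for t in tables:
            w.writerow(
                [t.tract_id, t.urban_area_id]
                + t.bracket_counts_all.tolist() + t.bracket_counts_black.tolist()
                + t.bracket_counts_white_nh.tolist()
                + [t.race_white_nh, t.race_black, t.race_total]
            )


def read_demographics_csv(path: str | Path) -> list[DemographicTable]:
    df = pd.read_csv(_require(path))
    if "tract_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'tract_id' column")
    all_cols = sorted(c for c in df.columns if c.startswith("all_b"))
    black_cols = sorted(c for c in df.columns if c.startswith("black_b"))
    white_cols = sorted(c for c in df.columns if c.startswith("whitenh_b"))
    if not all_cols:
        raise SchemaError(f"{path}: no all-race bracket columns (all_bNN)")
    if len(black_cols) != len(all_cols) or len(white_cols) != len(all_cols):
        missing = []
        if len(black_cols) != len(all_cols):
            missing.append("black_bNN")
        if len(white_cols) != len(all_cols):
            missing.append("whitenh_bNN")
        raise SchemaError(f"{path}: stratum bracket columns missing/partial: {missing}")
    tables = []
    for _, row in df.iterrows():
        tables.append(
            DemographicTable(
                tract_id=str(row["tract_id"]),
                urban_area_id=str(row.get("urban_area_id", "")),
                bracket_counts_all=row[all_cols].to_numpy(dtype=np.int64),
                bracket_counts_black=row[black_cols].to_numpy(dtype=np.int64),
                bracket_counts_white_nh=row[white_cols].to_numpy(dtype=np.int64),
                race_white_nh=int(row.get("race_white_nh", 0)),
                race_black=int(row.get("race_black", 0)),
                race_total=int(row.get("race_total", 0)),
            )
        )
    return tables
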