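"""Park geometry: sectioning by tract boundaries and size metrics.

A *park section* is the positive-area intersection of one park polygon
with one tract polygon — the unit that carries exposure weight.  Two
size-of-access metrics are computed per tract:

* ``percent_park`` — park-covered share of the tract area, with
  overlapping park footprints unioned first so the result never exceeds
  100%;
* ``largest_intersecting_park`` — the full (unclipped) area of the
  biggest park whose geometry intersects the tract, boundary touches
  included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree
from shapely.validation import make_valid

log = logging.getLogger(__name__)

#: intersections below this area (km^2) are treated as zero-area touches
AREA_EPS = 1e-12


@dataclass
class Tract:
    tract_id: str
    geometry: BaseGeometry
    urban_area_id: str = ""
    latent: Optional[float] = None  # synthetic truth, when known

    @property
    def area(self) -> float:
        return self.geometry.area


@dataclass
class ParkRecord:
    park_id: str
    name: str
    geometry: BaseGeometry
    area: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.area == 0.0:
            self.area = self.geometry.area


@dataclass
class ParkSection:
    park_id: str
    tract_id: str
    geometry: BaseGeometry
    area: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.area == 0.0:
            self.area = self.geometry.area


def repair_geometry(geom: BaseGeometry, feature_id: str = "?") -> Optional[BaseGeometry]:
    """One-shot validity repair; returns None for unrepairable features."""
    if geom is None or geom.is_empty:
        return None
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if fixed.is_valid and not fixed.is_empty:
        return fixed
    log.warning("dropping unrepairable geometry for feature %s", feature_id)
    return None


def _as_polygonal(geom: BaseGeometry) -> Optional[BaseGeometry]:
    """Keep only the polygonal part of a (possibly mixed) geometry."""
    if geom.is_empty:
        return None
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if polys:
            return shapely.union_all(polys)
    return None


def section_parks(parks: Sequence[ParkRecord], tracts: Sequence[Tract]) -> list[ParkSection]:
    """Split parks along tract boundaries into per-(park, tract) sections.

    Parks crossing administrative boundaries appear once per tract they
    overlap with positive area; zero-area touches produce no section.
    Invalid geometries are repaired once; unrepairable features raise.
    """
    clean_parks = []
    for p in parks:
        g = repair_geometry(p.geometry, p.park_id)
        if g is None:
            raise ValueError(f"invalid geometry for park {p.park_id!r} after repair")
        clean_parks.append(ParkRecord(p.park_id, p.name, g, p.area))
    tract_geoms = []
    for t in tracts:
        g = repair_geometry(t.geometry, t.tract_id)
        if g is None:
            raise ValueError(f"invalid geometry for tract {t.tract_id!r} after repair")
        tract_geoms.append(g)

    tree = STRtree(tract_geoms)
    sections: list[ParkSection] = []
    for p in clean_parks:
        for idx in tree.query(p.geometry, predicate="intersects"):
            inter = p.geometry.intersection(tract_geoms[idx])
            inter = _as_polygonal(inter)
            if inter is None or inter.area <= AREA_EPS:
                continue
            sections.append(ParkSection(p.park_id, tracts[idx].tract_id, inter))
    return sections


def percent_park(sections: Sequence[ParkSection], tract: Tract) -> float:
    """Percent of tract area covered by parks.

    Overlapping park footprints are unioned before dividing by the tract
    area, so the result is always in [0, 100].
    """
    if tract.area <= 0:
        raise ValueError(f"tract {tract.tract_id!r} has zero area")
    if not sections:
        return 0.0
    footprint = shapely.union_all([s.geometry for s in sections])
    return 100.0 * footprint.area / tract.area


def largest_intersecting_park(parks: Sequence[ParkRecord], tract: Tract) -> float:
    """Full area (km^2) of the largest park intersecting the tract.

    The intersects predicate includes boundary touches, and the area is
    the park's complete footprint, not the part inside the tract.
    Returns 0 when no park intersects.
    """
    best = 0.0
    for p in parks:
        if p.geometry.intersects(tract.geometry):
            best = max(best, p.area)
    return best


def size_metrics(parks: Sequence[ParkRecord], tracts: Sequence[Tract],
                 sections: Optional[Sequence[ParkSection]] = None) -> pd.DataFrame:
    """Per-tract size metrics table.

    Columns: tract_id, percent_park, largest_intersecting_park_area_km2,
    n_sections.  ``sections`` may be passed to avoid re-sectioning.
    """
    if sections is None:
        sections = section_parks(parks, tracts)
    by_tract: dict[str, list[ParkSection]] = {}
    for s in sections:
        by_tract.setdefault(s.tract_id, []).append(s)

    tree = STRtree([p.geometry for p in parks]) if parks else None
    rows = []
    for t in tracts:
        secs = by_tract.get(t.tract_id, [])
        if tree is not None:
            idxs = tree.query(t.geometry, predicate="intersects")
            largest = max((parks[i].area for i in idxs), default=0.0)
        else:
            largest = 0.0
        rows.append(
            {
                "tract_id": t.tract_id,
                "percent_park": percent_park(secs, t),
                "largest_intersecting_park_area_km2": largest,
                "n_sections": len(secs),
            }
        )
    return pd.DataFrame(rows)


def sections_by_tract(sections: Iterable[ParkSection]) -> dict[str, list[ParkSection]]:
    out: dict[str, list[ParkSection]] = {}
    for s in sections:
        out.setdefault(s.tract_id, []).append(s)
    return out
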