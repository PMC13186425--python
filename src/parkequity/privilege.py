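"""Neighborhood privilege via the Index of Concentration at the Extremes.

ICE = (most privileged - least privileged) / total for a small area,
ranging from -1 (entirely the least advantaged extreme) to +1 (entirely
the most advantaged extreme).  Three variants are supported:

* ``combined`` — most privileged: non-Hispanic-white householders in the
  top income brackets; least privileged: Black householders in the
  bottom income brackets; total: all-race householders.
* ``income``  — top/bottom bracket householders from the all-race table.
* ``race``    — non-Hispanic-white vs Black population counts.

Income cutpoints for "top/bottom ~20%" are selected by a running sum
over the pooled bracket counts: the contiguous prefix (suffix) whose
cumulative share is closest to the target is kept, including the extra
bracket on an exact tie.  Tracts are then ranked into privilege
quartiles within each urban area (quartile 1 = least privileged).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

VARIANTS = ("combined", "race", "income")


@dataclass
class DemographicTable:
    """Per-tract householder counts by income bracket, plus race counts.

    Bracket arrays share one ordering (lowest income first).  Stratum
    tables (Black, white non-Hispanic) must not exceed the all-race
    counts bracket-wise.
    """

    tract_id: str
    urban_area_id: str
    bracket_counts_all: np.ndarray
    bracket_counts_black: np.ndarray
    bracket_counts_white_nh: np.ndarray
    race_white_nh: int = 0
    race_black: int = 0
    race_total: int = 0

    def __post_init__(self) -> None:
        self.bracket_counts_all = np.asarray(self.bracket_counts_all, dtype=np.int64)
        self.bracket_counts_black = np.asarray(self.bracket_counts_black, dtype=np.int64)
        self.bracket_counts_white_nh = np.asarray(self.bracket_counts_white_nh, dtype=np.int64)
        n = len(self.bracket_counts_all)
        if len(self.bracket_counts_black) != n or len(self.bracket_counts_white_nh) != n:
            raise ValueError("stratum tables must share the all-race bracket ordering")
        for name, arr in (
            ("bracket_counts_all", self.bracket_counts_all),
            ("bracket_counts_black", self.bracket_counts_black),
            ("bracket_counts_white_nh", self.bracket_counts_white_nh),
        ):
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
        if np.any(self.bracket_counts_black + self.bracket_counts_white_nh
                  > self.bracket_counts_all):
            raise ValueError("stratum counts exceed all-race counts in some bracket")
        if min(self.race_white_nh, self.race_black, self.race_total) < 0:
            raise ValueError("race counts must be >= 0")


@dataclass
class IceCutpoints:
    low_brackets: tuple[int, ...]       # contiguous from the bottom of the ordering
    high_brackets: tuple[int, ...]      # contiguous from the top
    achieved_low_share: float
    achieved_high_share: float
    scope: str = "pooled"

    def __post_init__(self) -> None:
        if set(self.low_brackets) & set(self.high_brackets):
            raise ValueError("low and high bracket sets overlap")


@dataclass
class IceValue:
    tract_id: str
    urban_area_id: str
    variant: str
    ice: float                          # NaN = undefined (zero denominator)
    most_privileged_count: int
    least_privileged_count: int
    total_count: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ice)


@dataclass
class QuartileAssignment:
    tract_id: str
    urban_area_id: str
    variant: str
    quartile: int                       # 1 = least privileged ... 4 = most


def _closest_contiguous(counts: np.ndarray, target: float, from_top: bool,
                        max_k: Optional[int] = None) -> tuple[tuple[int, ...], float]:
    """Contiguous prefix/suffix whose cumulative share is closest to target.

    Ties include the extra bracket (overshoot tolerated).  Indices are
    returned in bracket order.  ``max_k`` caps the set size (used to keep
    the high set disjoint from an already-chosen low set).
    """
    total = counts.sum()
    order = counts[::-1] if from_top else counts
    cum = np.cumsum(order) / total
    n = len(counts)
    if max_k is None:
        max_k = n
    best_k, best_err = 0, math.inf
    for k in range(1, max_k + 1):
        err = abs(cum[k - 1] - target)
        if err < best_err or math.isclose(err, best_err, rel_tol=0, abs_tol=1e-12):
            best_k, best_err = k, min(err, best_err)
    if best_k == 0:
        raise ValueError("no admissible bracket set")
    if from_top:
        idx = tuple(range(n - best_k, n))
    else:
        idx = tuple(range(best_k))
    return idx, float(cum[best_k - 1])


def select_income_cutpoints(tables: Sequence[DemographicTable], target_share: float = 0.20,
                            scope: str = "pooled"):
    """Select the bottom/top income bracket sets nearest a target share.

    Pools the all-race bracket counts (across everything for
    ``scope='pooled'``, per urban area for ``scope='per_urban_area'``),
    forms running sums from each end of the bracket ordering, and keeps
    the contiguous set whose cumulative share is closest to
    ``target_share``; exact ties include the extra bracket.

    Returns an :class:`IceCutpoints` (pooled) or a dict keyed by urban
    area id (per-urban-area).
    """
    if not tables:
        raise ValueError("no demographic tables supplied")
    if not (0 < target_share < 0.5):
        raise ValueError("target_share must be in (0, 0.5)")
    if scope == "per_urban_area":
        out = {}
        for area in sorted({t.urban_area_id for t in tables}):
            sub = [t for t in tables if t.urban_area_id == area]
            out[area] = _cutpoints_pooled(sub, target_share, scope)
        return out
    if scope != "pooled":
        raise ValueError("scope must be 'pooled' or 'per_urban_area'")
    return _cutpoints_pooled(tables, target_share, scope)


def _cutpoints_pooled(tables: Sequence[DemographicTable], target_share: float,
                      scope: str) -> IceCutpoints:
    pooled = np.sum([t.bracket_counts_all for t in tables], axis=0)
    if pooled.sum() == 0:
        raise ValueError("no population: pooled bracket counts are all zero")
    low, low_share = _closest_contiguous(pooled, target_share, from_top=False)
    # the high set is searched over the brackets above the low set so the
    # two extremes stay disjoint even on highly skewed tables
    high, high_share = _closest_contiguous(pooled, target_share, from_top=True,
                                           max_k=len(pooled) - len(low))
    return IceCutpoints(low, high, low_share, high_share, scope)


def compute_ice(most: int, least: int, total: int) -> float:
    """(most - least) / total; NaN marks an undefined (empty-tract) value."""
    if most < 0 or least < 0 or total < 0:
        raise ValueError("counts must be non-negative")
    if total == 0:
        return float("nan")
    if most + least > total:
        raise ValueError("most + least exceeds total")
    return (most - least) / total


def compute_ice_table(tables: Sequence[DemographicTable],
                      cutpoints: Optional[IceCutpoints] = None,
                      variant: str = "combined") -> list[IceValue]:
    """ICE per tract for one variant.

    ``combined`` and ``income`` require cutpoints; ``race`` ignores them.
    Undefined values (zero denominator) are returned with NaN and can be
    filtered by ``.defined``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant in ("combined", "income") and cutpoints is None:
        raise ValueError(f"variant {variant!r} requires income cutpoints")
    out = []
    for t in tables:
        if variant == "combined":
            most = int(t.bracket_counts_white_nh[list(cutpoints.high_brackets)].sum())
            least = int(t.bracket_counts_black[list(cutpoints.low_brackets)].sum())
            total = int(t.bracket_counts_all.sum())
        elif variant == "income":
            most = int(t.bracket_counts_all[list(cutpoints.high_brackets)].sum())
            least = int(t.bracket_counts_all[list(cutpoints.low_brackets)].sum())
            total = int(t.bracket_counts_all.sum())
        else:  # race
            most, least, total = t.race_white_nh, t.race_black, t.race_total
        out.append(
            IceValue(t.tract_id, t.urban_area_id, variant,
                     compute_ice(most, least, total), most, least, total)
        )
    return out


def _quartile_sizes(n: int) -> list[int]:
    # ceiling-first: extras go to the lowest quartiles
    sizes = []
    remaining = n
    for k in range(4):
        s = math.ceil(remaining / (4 - k))
        sizes.append(s)
        remaining -= s
    return sizes


def assign_quartiles(ice_values: Sequence[IceValue]) -> tuple[list[QuartileAssignment], list[str]]:
    """Rank one urban area's tracts into privilege quartiles.

    Quartile 1 holds the lowest (least privileged) ICE values.  Ties are
    broken by stable tract-id order; quartile sizes differ by at most
    one, extras to the lower quartiles.  Tracts with undefined ICE are
    excluded and their ids returned alongside the assignments.

    Raises ``ValueError`` with fewer than 4 defined values.
    """
    areas = {v.urban_area_id for v in ice_values}
    if len(areas) > 1:
        raise ValueError("assign_quartiles expects a single urban area")
    excluded = [v.tract_id for v in ice_values if not v.defined]
    defined = [v for v in ice_values if v.defined]
    if len(defined) < 4:
        raise ValueError(f"too few tracts: {len(defined)} defined ICE values (< 4)")
    ranked = sorted(defined, key=lambda v: (v.ice, v.tract_id))
    sizes = _quartile_sizes(len(ranked))
    labels = np.repeat([1, 2, 3, 4], sizes)
    # warn when a tie straddles a quartile boundary: the split is then
    # an arbitrary (but reproducible) choice
    bounds = np.cumsum(sizes)[:-1]
    for b in bounds:
        if b < len(ranked) and ranked[b - 1].ice == ranked[b].ice:
            warnings.warn(
                "tied ICE values span a quartile boundary; split by tract-id order",
                stacklevel=2,
            )
            break
    assignments = [
        QuartileAssignment(v.tract_id, v.urban_area_id, v.variant, int(q))
        for v, q in zip(ranked, labels)
    ]
    return assignments, excluded


def ice_frame(values: Iterable[IceValue],
              assignments: Iterable[QuartileAssignment] = ()) -> pd.DataFrame:
    """Tabular view: tract_id, urban_area_id, variant, ice, quartile."""
    df = pd.DataFrame(
        [
            {
                "tract_id": v.tract_id,
                "urban_area_id": v.urban_area_id,
                "variant": v.variant,
                "ice": v.ice,
                "most_privileged_count": v.most_privileged_count,
                "least_privileged_count": v.least_privileged_count,
                "total_count": v.total_count,
            }
            for v in values
        ]
    )
    qmap = {(a.tract_id, a.variant): a.quartile for a in assignments}
    if len(df):
        df["quartile"] = [
            qmap.get((t, v), pd.NA) for t, v in zip(df["tract_id"], df["variant"])
        ]
    return df
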