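"""Quartile disparity statistics.

Tract-level park means are the unit of analysis: within one urban area
they are averaged by privilege quartile, the least (Q1) and most (Q4)
privileged quartiles are contrasted with a two-sided Welch t-test, and
the Q1-Q4 gap is additionally expressed as a percent difference
relative to the Q4 mean.  Across urban areas, per-quartile differences
from the urban mean are summarized by their median, and |Q1-Q4| gaps by
their mean and range.

No multiple-testing correction is applied across cities or variables;
the number of tests performed is recorded in the run log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

QUARTILES = (1, 2, 3, 4)
_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p_value: float) -> str:
    if math.isnan(p_value):
        return "none"
    for thresh, stars in _TIERS:
        if p_value < thresh:
            return stars
    return "none"


@dataclass
class DisparityResult:
    urban_area_id: str
    variant: str
    variable: str
    quartile_means: dict[int, float]
    quartile_n: dict[int, int]
    quartile_diff_from_urban: dict[int, float]   # quartile mean - urban mean
    q1_minus_q4: float
    percent_diff_q1_vs_q4: float
    t_stat: float
    df: float
    p_value: float
    urban_mean: float = float("nan")

    @property
    def significance(self) -> str:
        return significance_tier(self.p_value)


@dataclass
class CrossCitySummary:
    variable: str
    variant: str
    mean_abs_q1_q4_difference: float
    min_q1_q4_difference: float
    max_q1_q4_difference: float
    n_significant_q4_favored: int    # p < .05 and Q4 mean exceeds Q1 (q1_minus_q4 < 0)
    n_significant_q1_favored: int
    n_urban_areas: int


def quartile_means(values: Sequence[float], quartiles: Sequence[int]):
    """Arithmetic mean and count per privilege quartile.

    NaN values are excluded (tracts with undefined park means do not
    enter); an empty quartile yields a NaN mean.
    """
    values = np.asarray(values, dtype=float)
    quartiles = np.asarray(quartiles, dtype=int)
    if values.shape != quartiles.shape:
        raise ValueError("values and quartiles must align")
    means: dict[int, float] = {}
    ns: dict[int, int] = {}
    for q in QUARTILES:
        sel = (quartiles == q) & ~np.isnan(values)
        ns[q] = int(sel.sum())
        means[q] = float(values[sel].mean()) if ns[q] else float("nan")
    return means, ns


def welch_t(group_a: Sequence[float], group_b: Sequence[float]):
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, df, p) with the Welch-Satterthwaite degrees of freedom.
    Requires >= 2 observations per group and positive variance in at
    least one group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"degenerate groups: n = ({na}, {nb}), need >= 2 each")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate groups: zero variance in both groups")
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


def percent_diff_q1_q4(q1_mean: float, q4_mean: float) -> float:
    """100 * (Q1 - Q4) / Q4; positive means Q1 (least privileged) higher."""
    if q4_mean == 0 or math.isnan(q4_mean):
        return float("nan")
    return 100.0 * (q1_mean - q4_mean) / q4_mean


def compare_quartiles(values: Sequence[float], quartiles: Sequence[int],
                      urban_area_id: str = "", variant: str = "combined",
                      variable: str = "", urban_mean_value: float = float("nan"),
                      ) -> DisparityResult:
    """Full per-city disparity result for one variable.

    ``values`` are tract-level observations (park means or size metrics)
    aligned with quartile labels; NaN observations are dropped.  The
    Q1-vs-Q4 Welch test degrades to NaN statistics (rather than raising)
    when a group is degenerate, so sweeps over many small cities do not
    abort.
    """
    means, ns = quartile_means(values, quartiles)
    values = np.asarray(values, dtype=float)
    quartiles = np.asarray(quartiles, dtype=int)
    g1 = values[(quartiles == 1) & ~np.isnan(values)]
    g4 = values[(quartiles == 4) & ~np.isnan(values)]
    try:
        t, df, p = welch_t(g1, g4)
    except ValueError:
        t, df, p = float("nan"), float("nan"), float("nan")
    diff_urban = {
        q: (means[q] - urban_mean_value) if not math.isnan(urban_mean_value) else float("nan")
        for q in QUARTILES
    }
    return DisparityResult(
        urban_area_id=urban_area_id,
        variant=variant,
        variable=variable,
        quartile_means=means,
        quartile_n=ns,
        quartile_diff_from_urban=diff_urban,
        q1_minus_q4=means[1] - means[4],
        percent_diff_q1_vs_q4=percent_diff_q1_q4(means[1], means[4]),
        t_stat=t,
        df=df,
        p_value=p,
        urban_mean=urban_mean_value,
    )


def diff_from_urban_mean(results: Sequence[DisparityResult]) -> pd.DataFrame:
    """Distribution, across urban areas, of quartile mean minus urban mean.

    One row per quartile with the median and interquartile spread of the
    per-city differences — the numbers behind a boxplot-by-quartile
    display.
    """
    rows = []
    for q in QUARTILES:
        diffs = np.array(
            [r.quartile_diff_from_urban[q] for r in results], dtype=float
        )
        diffs = diffs[~np.isnan(diffs)]
        rows.append(
            {
                "quartile": q,
                "n_urban_areas": len(diffs),
                "median_diff": float(np.median(diffs)) if len(diffs) else float("nan"),
                "q25_diff": float(np.percentile(diffs, 25)) if len(diffs) else float("nan"),
                "q75_diff": float(np.percentile(diffs, 75)) if len(diffs) else float("nan"),
                "min_diff": float(diffs.min()) if len(diffs) else float("nan"),
                "max_diff": float(diffs.max()) if len(diffs) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def cross_city_summary(results: Sequence[DisparityResult]) -> CrossCitySummary:
    """Mean |Q1-Q4| gap, its range, and significant-city counts by sign."""
    if not results:
        raise ValueError("no per-city results supplied")
    variable = results[0].variable
    variant = results[0].variant
    diffs = np.array([r.q1_minus_q4 for r in results], dtype=float)
    ok = ~np.isnan(diffs)
    sig = np.array([(r.p_value < 0.05) if not math.isnan(r.p_value) else False
                    for r in results])
    return CrossCitySummary(
        variable=variable,
        variant=variant,
        mean_abs_q1_q4_difference=float(np.abs(diffs[ok]).mean()) if ok.any() else float("nan"),
        min_q1_q4_difference=float(diffs[ok].min()) if ok.any() else float("nan"),
        max_q1_q4_difference=float(diffs[ok].max()) if ok.any() else float("nan"),
        n_significant_q4_favored=int((sig & (diffs < 0)).sum()),
        n_significant_q1_favored=int((sig & (diffs > 0)).sum()),
        n_urban_areas=len(results),
    )


def disparity_frame(results: Iterable[DisparityResult]) -> pd.DataFrame:
    """One row per (urban_area, variant, variable) with all result fields."""
    rows = []
    for r in results:
        row = {
            "urban_area_id": r.urban_area_id,
            "variant": r.variant,
            "variable": r.variable,
            "urban_mean": r.urban_mean,
            "q1_minus_q4": r.q1_minus_q4,
            "percent_diff_q1_vs_q4": r.percent_diff_q1_vs_q4,
            "t_stat": r.t_stat,
            "df": r.df,
            "p_value": r.p_value,
            "significance": r.significance,
        }
        for q in QUARTILES:
            row[f"q{q}_mean"] = r.quartile_means[q]
            row[f"q{q}_n"] = r.quartile_n[q]
            row[f"q{q}_diff_from_urban"] = r.quartile_diff_from_urban[q]
        rows.append(row)
    return pd.DataFrame(rows)
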