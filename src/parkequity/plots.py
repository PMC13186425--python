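"""Result plots: size by quartile, exposure difference boxplots, Q1-vs-Q4.

These reproduce the three standard displays of the analysis from the
result tables: per-city quartile dot plots of the size metrics with
significance stars, per-quartile boxplots of park-minus-urban-mean
differences across cities, and a per-city percent-difference chart
contrasting the least (Q1) and most (Q4) privileged quartiles.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

QCOLORS = {1: "#d7301f", 2: "#fc8d59", 3: "#91bfdb", 4: "#0570b0"}


def plot_size_by_quartile(disparities: pd.DataFrame, variable: str, path: str) -> None:
    """Dot plot of quartile means per urban area for one size metric."""
    sub = disparities[disparities["variable"] == variable]
    order = sub.sort_values("urban_mean", ascending=False)
    fig, ax = plt.subplots(figsize=(7, max(2, 0.4 * len(sub) + 1)))
    for i, (_, r) in enumerate(order.iterrows()):
        for q in (1, 2, 3, 4):
            ax.plot(r[f"q{q}_mean"], i, "o", color=QCOLORS[q], ms=7)
        label = f'{r["urban_area_id"]} {r["significance"] if r["significance"] != "none" else ""}'
        ax.text(-0.01, i, label, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel(variable)
    ax.set_title(f"{variable} by privilege quartile (Q1 least .. Q4 most)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diff_from_urban(disparities: pd.DataFrame, variables: Sequence[str],
                         path: str) -> None:
    """Boxplots of quartile park mean minus urban mean, across cities."""
    fig, axes = plt.subplots(1, len(variables), figsize=(3 * len(variables), 4),
                             squeeze=False)
    for ax, var in zip(axes[0], variables):
        sub = disparities[disparities["variable"] == var]
        data = [sub[f"q{q}_diff_from_urban"].dropna().to_numpy() for q in (1, 2, 3, 4)]
        bp = ax.boxplot(data, patch_artist=True, tick_labels=["Q1", "Q2", "Q3", "Q4"])
        for patch, q in zip(bp["boxes"], (1, 2, 3, 4)):
            patch.set_facecolor(QCOLORS[q])
        ax.axhline(0.0, color="red", ls=":", lw=1)
        ax.set_title(var, fontsize=9)
    axes[0][0].set_ylabel("park mean - urban mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_percent_diff_q1_q4(disparities: pd.DataFrame, variables: Sequence[str],
                            path: str) -> None:
    """Per-city percent difference between Q1 and Q4 park means.

    Symbols right of the zero line mean Q1 (least privileged) values were
    higher; filled markers are significant at p < .05.
    """
    cities = sorted(disparities["urban_area_id"].unique())
    fig, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(cities) + 1)))
    cmap = plt.get_cmap("tab10")
    for vi, var in enumerate(variables):
        sub = disparities[disparities["variable"] == var].set_index("urban_area_id")
        for ci, city in enumerate(cities):
            if city not in sub.index:
                continue
            r = sub.loc[city]
            sig = r["p_value"] < 0.05
            ax.plot(r["percent_diff_q1_vs_q4"], ci,
                    marker="o" if sig else "^",
                    mfc=cmap(vi) if sig else "none", mec=cmap(vi),
                    ls="none", label=var if ci == 0 else None)
    ax.axvline(0.0, color="red", ls=":", lw=1)
    ax.set_yticks(range(len(cities)), cities, fontsize=8)
    ax.set_xlabel("percent difference, Q1 vs Q4 (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
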