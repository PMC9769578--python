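"""Minimal figures: stacked process fractions and Mantel correlograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .classify import PROCESSES

_COLORS = {
    "homogeneous_selection": "#1b7837",
    "heterogeneous_selection": "#a6dba0",
    "dispersal_limitation": "#9970ab",
    "homogenizing_dispersal": "#c2a5cf",
    "drift": "#bdbdbd",
}


def plot_process_fractions(summaries: pd.DataFrame, path: str) -> None:
    """Stacked bars of the five process fractions per group."""
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(summaries)), 4))
    bottom = None
    for proc in PROCESSES:
        vals = summaries[f"frac_{proc}"].fillna(0.0)
        ax.bar(summaries["group"], vals, bottom=bottom,
               label=proc.replace("_", " "), color=_COLORS[proc])
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("fraction of sample pairs")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, loc="upper right")
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlogram(cg: pd.DataFrame, path: str, variable: str = "env") -> None:
    """Mantel r per phylogenetic distance class, filled when significant."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    sig = cg["significant"].fillna(False).astype(bool)
    ax.plot(cg["midpoint"], cg["r"], "-", color="k", lw=1)
    ax.scatter(cg.loc[sig, "midpoint"], cg.loc[sig, "r"], c="k", zorder=3,
               label="significant")
    ax.scatter(cg.loc[~sig, "midpoint"], cg.loc[~sig, "r"], facecolors="white",
               edgecolors="k", zorder=3, label="n.s.")
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("phylogenetic distance class midpoint")
    ax.set_ylabel("Mantel r (positive = similar niches)")
    ax.set_title(variable)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
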