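"""Minimal figure helpers for the main result tables.

Each function draws on a provided (or fresh) matplotlib Axes and returns
it; styling is deliberately plain and left to the caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def preference_heatmap(table: pd.DataFrame, value: str = "roe", ax=None):
    """Subsets x tissues heatmap of the tissue-preference table (Ro/e or OR)."""
    pivot = table.pivot(index="subset", columns="tissue", values=value)
    ax = _axes(ax)
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.figure.colorbar(im, ax=ax, label=value)
    ax.set_title(f"tissue preference ({value})")
    return ax


def polarization_butterfly(table: pd.DataFrame, axis1: str, axis2: str, ax=None):
    """Back-to-back bars of two opposing per-cluster functional scores."""
    ax = _axes(ax)
    y = np.arange(len(table))
    ax.barh(y, -table[axis1].to_numpy(), color="#c0504d", label=axis1)
    ax.barh(y, table[axis2].to_numpy(), color="#4f81bd", label=axis2)
    ax.set_yticks(y, table["cluster"])
    ax.axvline(0.0, color="black", lw=0.8)
    ax.set_xlabel("mean set score")
    ax.legend()
    return ax


def km_curves(result, ax=None):
    """Step plot of the Kaplan-Meier curves in a SurvivalResult."""
    ax = _axes(ax)
    for group, curve in result.km_curves.items():
        ax.step(curve.index, curve["survival"], where="post", label=group)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {result.logrank_p:.2g}"
              if np.isfinite(result.logrank_p) else None)
    return ax


def dbi_trace(trace, ax=None):
    """Davies-Bouldin index across the resolution / k grid."""
    ax = _axes(ax)
    table = trace.table.dropna(subset=["dbi"])
    ax.plot(table["resolution"], table["dbi"], marker="o")
    ax.axvline(trace.selected, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("resolution / k")
    ax.set_ylabel("Davies-Bouldin index")
    return ax
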