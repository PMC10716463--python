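"""Tissue-preference statistics for cell subsets: odds ratios, Fisher tests, Ro/e.

For every (subset i, tissue j) pair a 2x2 table is formed — subset-i cells
in tissue j (a), subset-i cells elsewhere (b), other cells in j (c), other
cells elsewhere (d). The sample odds ratio (a*d)/(b*c) with a two-sided
Fisher exact p quantifies preference; p-values are BH-adjusted across all
pairs. OR > 1.5 labels the pair "enriched", OR < 0.5 "depleted". The
companion Ro/e statistic is the observed/expected count ratio a / (row_i *
col_j / total).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = ["tissue_preference", "bh_adjust"]


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """(a*d)/(b*c) with a Haldane 0.5 correction iff any cell is zero."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), corrected


def tissue_preference(
    cells: pd.DataFrame,
    or_high: float = 1.5,
    or_low: float = 0.5,
) -> pd.DataFrame:
    """Per (subset, tissue) odds-ratio preference table.

    Parameters
    ----------
    cells
        One row per cell with columns ``subset`` and ``tissue``.
    or_high, or_low
        Label thresholds: OR strictly above ``or_high`` -> "enriched",
        strictly below ``or_low`` -> "depleted", else "none".

    Returns
    -------
    DataFrame with columns subset, tissue, a, b, c, d, odds_ratio,
    haldane_corrected, p, q, roe, label.
    """
    if not {"subset", "tissue"}.issubset(cells.columns):
        raise ValueError("cells table needs 'subset' and 'tissue' columns")
    counts = cells.groupby(["subset", "tissue"]).size().unstack(fill_value=0)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 subsets and 2 tissues")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("a subset or tissue has zero cells")
    total = int(counts.to_numpy().sum())
    row_totals = counts.sum(axis=1)
    col_totals = counts.sum(axis=0)

    rows = []
    for subset in counts.index:
        for tissue in counts.columns:
            a = int(counts.loc[subset, tissue])
            b = int(row_totals[subset] - a)
            c = int(col_totals[tissue] - a)
            d = int(total - a - b - c)
            odds, corrected = _sample_odds_ratio(a, b, c, d)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            roe = a / (row_totals[subset] * col_totals[tissue] / total)
            rows.append(
                {"subset": subset, "tissue": tissue, "a": a, "b": b, "c": c, "d": d,
                 "odds_ratio": odds, "haldane_corrected": corrected,
                 "p": float(p), "roe": float(roe)}
            )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["label"] = np.select(
        [table["odds_ratio"] > or_high, table["odds_ratio"] < or_low],
        ["enriched", "depleted"],
        default="none",
    )
    return table
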