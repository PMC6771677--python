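"""Cross-dataset region categories and prediction-hardness analysis.

Regions assayed in two cell types are categorized by the 2x2 of their binary
activity calls: active in both (common), active only in one
(cell-type-specific), or inactive in both. A region's *hardness* under a
classifier is the rank-normalized absolute difference between its binary
label and the predicted probability — 0 for the easiest region, 1 for the
hardest — which makes hardness comparable across models and datasets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["categorize_regions", "hardness", "compare_hardness"]

CATEGORIES = ("common_active", "specific_to_A", "specific_to_B", "inactive_both")


def categorize_regions(labels_a: pd.Series, labels_b: pd.Series) -> pd.Series:
    """Category of each shared region from the two binary label vectors."""
    if set(labels_a.index) != set(labels_b.index):
        only_a = sorted(set(labels_a.index) - set(labels_b.index))[:5]
        only_b = sorted(set(labels_b.index) - set(labels_a.index))[:5]
        raise ValueError(
            f"region id sets differ (only in A: {only_a}; only in B: {only_b})"
        )
    lb = labels_b.loc[labels_a.index]
    a = labels_a.astype(bool)
    b = lb.astype(bool)
    cat = pd.Series("inactive_both", index=labels_a.index, name="category")
    cat[a & b] = "common_active"
    cat[a & ~b] = "specific_to_A"
    cat[~a & b] = "specific_to_B"
    return cat


def hardness(pred_prob: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Rank-normalized |label - predicted probability| per region.

    Raw differences are ranked with average ranks for ties and mapped to
    ``(rank - 1) / (n - 1)`` in [0, 1]; any strictly increasing transform of
    the raw differences yields the same hardness.
    """
    p = np.asarray(pred_prob, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if len(p) < 2:
        raise ValueError("need at least 2 regions")
    raw = np.abs(np.asarray(labels, float) - p)
    ranks = stats.rankdata(raw, method="average")
    h = (ranks - 1.0) / (len(raw) - 1.0)
    return pd.DataFrame(
        {"raw": raw, "hardness": h}, index=pred_prob.index
    )


def compare_hardness(
    hardness_table: pd.DataFrame,
    categories: pd.Series,
    min_size: int = 10,
) -> dict:
    """Per-category hardness ECDFs and pairwise two-sample KS tests.

    Categories with fewer than ``min_size`` regions are excluded (listed
    under ``"excluded"``). ECDFs are sampled at every observed hardness
    value.
    """
    h = hardness_table["hardness"]
    cats = categories.loc[h.index]
    groups = {c: h[cats == c].to_numpy() for c in cats.unique()}
    excluded = sorted(c for c, v in groups.items() if len(v) < min_size)
    groups = {c: v for c, v in groups.items() if len(v) >= min_size}
    if len(groups) < 2:
        raise ValueError("need >= 2 categories with enough regions")

    grid = np.sort(h.to_numpy())
    ecdf = pd.DataFrame(
        {c: np.searchsorted(np.sort(v), grid, side="right") / len(v) for c, v in groups.items()},
        index=pd.Index(grid, name="hardness"),
    )
    rows = []
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.ks_2samp(groups[a], groups[b])
            rows.append((a, b, float(res.statistic), float(res.pvalue)))
    ks = pd.DataFrame(rows, columns=["category_a", "category_b", "ks_statistic", "p"])
    medians = pd.Series({c: float(np.median(v)) for c, v in groups.items()}, name="median_hardness")
    return {"ecdf": ecdf, "ks": ks, "medians": medians, "excluded": excluded}
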