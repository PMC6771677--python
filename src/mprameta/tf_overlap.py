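"""Predictive transcription factors and their overlap between datasets.

A TF is *predictive* in a dataset when its per-region predicted-binding score
is significantly Spearman-correlated with MPRA activity (BH q < 0.05 across
TFs); *high-confidence* at q < 0.01 and *nonpredictive* at q > 0.1. Overlap
of predictive sets between datasets is tested with an upper-tail
hypergeometric p-value over the jointly scored TF universe, and TF
predictivity is related to expression with a Wilcoxon rank-sum test of the
TPM of the best- vs worst-ranked factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import bh_adjust

__all__ = [
    "predictive_tfs",
    "overlap_enrichment",
    "expression_association",
    "difference_tfs",
]


def predictive_tfs(
    tf_scores: pd.DataFrame,
    activity: pd.Series,
    q_predictive: float = 0.05,
    q_high_confidence: float = 0.01,
    q_nonpredictive: float = 0.1,
) -> pd.DataFrame:
    """Per-TF Spearman correlation with activity and membership calls.

    Returns a frame indexed by TF with columns ``rho, p, q, membership``
    where membership is one of predictive / high_confidence (a subset of
    predictive, reported as high_confidence) / nonpredictive / indeterminate.
    Constant score columns have undefined correlation and are marked
    indeterminate.
    """
    if len(activity) < 8:
        raise ValueError("need >= 8 regions")
    act = activity.loc[tf_scores.index].to_numpy(float)
    rows = {}
    for tf in tf_scores.columns:
        x = tf_scores[tf].to_numpy(float)
        if np.all(x == x[0]):
            rows[tf] = (np.nan, np.nan)
            continue
        rho, p = stats.spearmanr(x, act)
        rows[tf] = (float(rho), float(p))
    out = pd.DataFrame(rows, index=["rho", "p"]).T
    valid = out["p"].notna()
    out["q"] = np.nan
    out.loc[valid, "q"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["predictive"] = out["q"] < q_predictive
    out["high_confidence"] = out["q"] < q_high_confidence
    out["nonpredictive"] = out["q"] > q_nonpredictive
    member = pd.Series("indeterminate", index=out.index, name="membership")
    member[out["predictive"]] = "predictive"
    member[out["high_confidence"]] = "high_confidence"
    member[out["nonpredictive"]] = "nonpredictive"
    out["membership"] = member
    return out


def overlap_enrichment(set_a: set, set_b: set, universe_size: int) -> dict:
    """Fold enrichment and upper-tail hypergeometric p of a set overlap.

    fold = |A∩B| * N / (|A| * |B|); p = P(X >= |A∩B|) for X hypergeometric
    with population N, |A| successes, |B| draws.
    """
    na, nb = len(set_a), len(set_b)
    if na > universe_size or nb > universe_size:
        raise ValueError("set larger than the universe")
    overlap = len(set_a & set_b)
    if na == 0 or nb == 0:
        return {"overlap": overlap, "fold": np.nan, "p": np.nan, "undefined": True}
    fold = overlap * universe_size / (na * nb)
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, na, nb))
    return {"overlap": overlap, "fold": float(fold), "p": p, "undefined": False}


def pairwise_overlap(
    sets: dict[str, set], universes: dict[tuple[str, str], int]
) -> pd.DataFrame:
    """overlap_enrichment over every dataset pair with BH across pairs."""
    rows = []
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            n = universes[(a, b)] if (a, b) in universes else universes[(b, a)]
            res = overlap_enrichment(sets[a], sets[b], n)
            rows.append((a, b, res["overlap"], res["fold"], res["p"]))
    out = pd.DataFrame(rows, columns=["dataset_a", "dataset_b", "overlap", "fold", "p"])
    valid = out["p"].notna()
    out["q"] = np.nan
    out.loc[valid, "q"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


def expression_association(
    tf_ranks: pd.Series, tpm: pd.Series, k: int = 50
) -> dict:
    """Wilcoxon rank-sum test: TPM of the k best- vs k worst-ranked TFs.

    TFs without a TPM value are dropped and k is reduced symmetrically so the
    two groups stay the same size. Two-sided p.
    """
    ranked = tf_ranks.sort_values()  # rank 1 = most predictive
    have_tpm = ranked.index.intersection(tpm.dropna().index)
    dropped = len(ranked) - len(have_tpm)
    ranked = ranked.loc[[i for i in ranked.index if i in set(have_tpm)]]
    k_eff = min(k, len(ranked) // 2)
    if k_eff < 1:
        raise ValueError("not enough TFs with expression values")
    top = tpm.loc[ranked.index[:k_eff]].to_numpy(float)
    bottom = tpm.loc[ranked.index[-k_eff:]].to_numpy(float)
    res = stats.mannwhitneyu(top, bottom, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "k": k_eff,
        "n_dropped": dropped,
    }


def difference_tfs(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict[str, list[str]]:
    """TFs high-confidence in one dataset and nonpredictive in the other."""
    common = set_a.index.intersection(set_b.index)
    a_specific = sorted(
        common[
            set_a.loc[common, "high_confidence"] & set_b.loc[common, "nonpredictive"]
        ]
    )
    b_specific = sorted(
        common[
            set_b.loc[common, "high_confidence"] & set_a.loc[common, "nonpredictive"]
        ]
    )
    return {"A_specific": a_specific, "B_specific": b_specific}
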