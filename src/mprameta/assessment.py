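"""Feature predictivity assessment: nine tests, ranks, and robustness.

Seven *regression tests* measure how well a feature (or model prediction)
tracks quantitative MPRA activity: Pearson, Spearman and Kendall correlation
on all regions, the same three restricted to the top activity quartile, and
Spearman against the quintile index of activity. Two *classification tests*
(AUROC and AUPRC) measure separation of active from inactive regions; their
significance comes from a two-sample Kolmogorov-Smirnov test of the scores of
positive- vs negative-labelled regions.

Features are ranked per test (absolute statistic, descending, average-rank
ties), the within-dataset rank is the median of the per-test ranks, and the
comprehensive rank is the median of within-dataset ranks across datasets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .quantify import bh_adjust

__all__ = [
    "REGRESSION_TESTS",
    "CLASSIFICATION_TESTS",
    "regression_tests",
    "classification_tests",
    "feature_test_suite",
    "within_dataset_rank",
    "comprehensive_rank",
    "subsample_robustness",
    "shuffled_mean_control",
]

REGRESSION_TESTS = (
    "pearson",
    "spearman",
    "kendall",
    "pearson_top25",
    "spearman_top25",
    "kendall_top25",
    "spearman_quintile",
)
CLASSIFICATION_TESTS = ("auroc", "auprc")


def _corr(fn, x, y) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0  # undefined: flagged as null
    r, p = fn(x, y)
    if not np.isfinite(r):
        return 0.0, 1.0
    return float(r), float(p)


def quintile_index(y: np.ndarray) -> np.ndarray:
    """Quintile bin (0-4) of each value by empirical quantiles, ties to lower bin."""
    y = np.asarray(y, float)
    edges = np.quantile(y, [0.2, 0.4, 0.6, 0.8])
    # value equal to an edge goes to the lower bin
    return np.searchsorted(edges, y, side="left")


def regression_tests(x, y) -> pd.DataFrame:
    """The seven regression-test statistics of x against activity y.

    Returns a frame indexed by test name with columns ``statistic, p``.
    Constant x (overall or within a subset) yields statistic 0 with p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 8:
        raise ValueError(f"need n >= 8, got {len(x)}")
    if len(np.unique(y)) < 2:
        raise ValueError("activity y must have at least 2 distinct values")
    res = {}
    res["pearson"] = _corr(stats.pearsonr, x, y)
    res["spearman"] = _corr(stats.spearmanr, x, y)
    res["kendall"] = _corr(stats.kendalltau, x, y)
    top = y >= np.quantile(y, 0.75)
    res["pearson_top25"] = _corr(stats.pearsonr, x[top], y[top])
    res["spearman_top25"] = _corr(stats.spearmanr, x[top], y[top])
    res["kendall_top25"] = _corr(stats.kendalltau, x[top], y[top])
    res["spearman_quintile"] = _corr(stats.spearmanr, x, quintile_index(y))
    return pd.DataFrame(res, index=["statistic", "p"]).T.loc[list(REGRESSION_TESTS)]


def classification_tests(scores, labels) -> pd.DataFrame:
    """AUROC, AUPRC and the positives-vs-negatives KS p-value.

    Returns a frame indexed by {auroc, auprc} with columns ``statistic, p``;
    both tests share the KS p-value, which compares the score distribution of
    positive-labelled items against the negatives.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    pos, neg = scores[labels == 1], scores[labels == 0]
    ks_p = float(stats.ks_2samp(pos, neg).pvalue)
    return pd.DataFrame(
        {"statistic": [auroc, auprc], "p": [ks_p, ks_p]},
        index=list(CLASSIFICATION_TESTS),
    )


def feature_test_suite(
    features: pd.DataFrame, activity: pd.Series, labels: pd.Series | None = None
) -> pd.DataFrame:
    """Run all applicable tests for every feature column.

    Returns a long frame (feature, test, statistic, p, q) with q-values
    Benjamini-Hochberg-adjusted within each test across features.
    """
    rows = []
    for feat in features.columns:
        x = features[feat]
        reg = regression_tests(x, activity)
        for test, r in reg.iterrows():
            rows.append((feat, test, r["statistic"], r["p"]))
        if labels is not None and labels.nunique() == 2:
            cls = classification_tests(x, labels)
            for test, r in cls.iterrows():
                rows.append((feat, test, r["statistic"], r["p"]))
    out = pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
    out["q"] = np.nan
    for test, idx in out.groupby("test").groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def within_dataset_rank(suite: pd.DataFrame) -> pd.Series:
    """Median of the per-test feature ranks.

    Correlation statistics rank by absolute value (a strong negative feature
    is as predictive as a positive one); AUROC/AUPRC rank as-is. Rank 1 is
    best; ties get average ranks.
    """
    n_features = suite["feature"].nunique()
    if n_features < 2:
        raise ValueError("need >= 2 features to rank")
    ranks = []
    for test, grp in suite.groupby("test"):
        key = (
            grp["statistic"]
            if test in CLASSIFICATION_TESTS
            else grp["statistic"].abs()
        )
        r = key.rank(ascending=False, method="average")
        ranks.append(pd.Series(r.to_numpy(), index=grp["feature"], name=test))
    rank_table = pd.concat(ranks, axis=1)
    return rank_table.median(axis=1).rename("within_dataset_rank")


def comprehensive_rank(per_dataset_ranks: dict[str, pd.Series]) -> pd.DataFrame:
    """Median of within-dataset ranks across datasets, sorted best-first.

    Features absent from a dataset are excluded from that median; a feature
    absent from every dataset is dropped with a diagnostic column is not
    needed because the concat simply has no row for it.
    """
    if not per_dataset_ranks:
        raise ValueError("need at least one dataset")
    table = pd.DataFrame(per_dataset_ranks)
    all_missing = table.isna().all(axis=1)
    table = table[~all_missing]
    out = table.copy()
    out["comprehensive_rank"] = table.median(axis=1, skipna=True)
    return out.sort_values("comprehensive_rank")


def subsample_robustness(
    x,
    y,
    labels=None,
    n_rep: int = 100,
    frac: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and sd of every test statistic over seeded subsamples.

    Each repetition samples ``frac`` of the regions without replacement and
    recomputes the regression (and, when labels are given, classification)
    statistics.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    m = int(round(frac * n))
    if m < 8:
        raise ValueError(f"frac * n = {m} < 8")
    rng = np.random.default_rng(seed)
    stats_acc: dict[str, list[float]] = {}
    for _ in range(n_rep):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        reg = regression_tests(x[idx], y[idx])
        for test, r in reg.iterrows():
            stats_acc.setdefault(test, []).append(r["statistic"])
        if labels is not None:
            lab = np.asarray(labels, int)[idx]
            if len(np.unique(lab)) == 2:
                cls = classification_tests(x[idx], lab)
                for test, r in cls.iterrows():
                    stats_acc.setdefault(test, []).append(r["statistic"])
    return pd.DataFrame(
        {
            "mean": {t: float(np.mean(v)) for t, v in stats_acc.items()},
            "sd": {t: float(np.std(v, ddof=0)) for t, v in stats_acc.items()},
        }
    )


def shuffled_mean_control(
    cell_track_values: pd.DataFrame,
    pool_track_values: pd.DataFrame,
    activity: pd.Series,
    n_draws: int = 100,
    seed: int = 0,
    statistic: str = "spearman",
) -> dict[str, float]:
    """Empirical p-value for cell-type specificity of the cell-mean feature.

    The observed statistic is the predictivity (|Spearman| by default) of the
    mean over the cell-type-specific tracks. Each draw picks the same number
    of tracks at random from the non-cell-type pool, forms their mean
    feature, and recomputes the statistic; the empirical p is the fraction of
    draws at least as predictive as the cell-specific feature.
    """
    n_cell = cell_track_values.shape[1]
    if pool_track_values.shape[1] < n_cell:
        raise ValueError(
            f"pool has {pool_track_values.shape[1]} tracks < cell set size {n_cell}"
        )

    def stat(feature: np.ndarray) -> float:
        r, _ = _corr(stats.spearmanr, feature, activity.to_numpy(float))
        return abs(r)

    observed = stat(cell_track_values.mean(axis=1).to_numpy())
    rng = np.random.default_rng(seed)
    cols = np.asarray(pool_track_values.columns)
    draws = []
    for _ in range(n_draws):
        chosen = rng.choice(cols, size=n_cell, replace=False)
        draws.append(stat(pool_track_values[chosen].mean(axis=1).to_numpy()))
    draws = np.asarray(draws)
    return {
        "observed": observed,
        "empirical_p": float(np.mean(draws >= observed)),
        "n_draws": float(n_draws),
    }
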