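"""Nine-test statistics, rank aggregation, and robustness procedures."""

import numpy as np
import pandas as pd
import pytest

from mprameta import assessment
from mprameta.assessment import (
    classification_tests,
    comprehensive_rank,
    feature_test_suite,
    regression_tests,
    shuffled_mean_control,
    subsample_robustness,
    within_dataset_rank,
)


def brute_kendall(x, y):
    """O(n^2) concordant/discordant pair counting (tau-b with tie correction)."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def brute_auroc(scores, labels):
    """Pair counting with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRegressionTests:
    def test_perfect_reversal_kendall(self):
        res = regression_tests([1, 2, 3, 4, 5, 6, 7, 8], [8, 7, 6, 5, 4, 3, 2, 1])
        assert res.loc["kendall", "statistic"] == pytest.approx(-1.0)

    def test_identity_all_statistics_one(self):
        x = np.arange(1, 13, dtype=float)
        res = regression_tests(x, x)
        six = [t for t in res.index if t != "spearman_quintile"]
        np.testing.assert_allclose(res.loc[six, "statistic"], 1.0)
        # binning introduces ties, so Spearman against the quintile index
        # cannot reach exactly 1 for strictly increasing data
        assert res.loc["spearman_quintile", "statistic"] > 0.95

    def test_kendall_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res = regression_tests(x, y)
        assert res.loc["kendall", "statistic"] == pytest.approx(brute_kendall(x, y))

    def test_constant_feature_flagged_null(self):
        res = regression_tests(np.ones(10), np.arange(10, dtype=float))
        assert res.loc["pearson", "statistic"] == 0.0
        assert res.loc["pearson", "p"] == 1.0

    def test_top25_subset_uses_activity_quantile(self):
        # signal only among the top quarter of y
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(0, 0.1, 30), np.linspace(5, 6, 10)])
        x = np.concatenate([rng.normal(size=30), np.linspace(0, 1, 10)])
        res = regression_tests(x, y)
        assert res.loc["spearman_top25", "statistic"] > 0.9

    def test_quintile_binning_ties_to_lower(self):
        q = assessment.quintile_index(np.arange(10, dtype=float))
        assert q.min() == 0 and q.max() == 4
        assert (np.diff(q) >= 0).all()


class TestClassificationTests:
    def test_worked_auroc_example(self):
        res = classification_tests([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert res.loc["auroc", "statistic"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        scores = np.concatenate([np.zeros(5), np.ones(5)])
        labels = scores.astype(int)
        res = classification_tests(scores, labels)
        assert res.loc["auroc", "statistic"] == 1.0
        assert res.loc["auprc", "statistic"] == 1.0

    def test_auroc_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(23)
        scores = rng.integers(0, 10, size=50).astype(float)  # forces ties
        labels = rng.integers(0, 2, size=50)
        res = classification_tests(scores, labels)
        assert res.loc["auroc", "statistic"] == pytest.approx(
            brute_auroc(scores, labels)
        )

    def test_auroc_invariant_to_score_shift(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        r1 = classification_tests(scores, labels)
        r2 = classification_tests(scores + 100.0, labels)
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            classification_tests([0.1, 0.2, 0.3], [1, 1, 1])


class TestRanking:
    def _suite(self, stats_by_feature):
        rows = []
        tests = list(assessment.REGRESSION_TESTS) + list(assessment.CLASSIFICATION_TESTS)
        for feat, per_test in stats_by_feature.items():
            for t, s in zip(tests, per_test):
                rows.append((feat, t, s, 0.5))
        return pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])

    def test_unanimous_winner_rank_one(self):
        suite = self._suite({"best": [0.9] * 9, "mid": [0.5] * 9, "low": [0.1] * 9})
        ranks = within_dataset_rank(suite)
        assert ranks["best"] == 1.0

    def test_median_of_mixed_ranks(self):
        # feature ranks [1,1,1,1,2,2,9,9,9] over nine tests -> median 2
        per_test = {}
        feats = [f"f{i}" for i in range(9)]
        # craft statistics so 'target' gets exactly those ranks
        target_ranks = [1, 1, 1, 1, 2, 2, 9, 9, 9]
        rows = []
        tests = list(assessment.REGRESSION_TESTS) + list(assessment.CLASSIFICATION_TESTS)
        for t_i, t in enumerate(tests):
            want = target_ranks[t_i]
            stats = {}
            stats["target"] = 1.0 - (want - 1) * 0.1
            others = [f for f in feats if f != "f0"]
            fill = [v for v in np.linspace(1.0, 0.1, 10) if not np.isclose(v, stats["target"])]
            k = 0
            for f in feats:
                stats[f] = fill[k]
                k += 1
            # ensure exactly want-1 features above target
            vals = sorted(fill, reverse=True)
            above = vals[: want - 1]
            below = vals[want - 1 : want - 1 + len(feats)]
            for f, v in zip(feats[: want - 1], above):
                stats[f] = v
            for f, v in zip(feats[want - 1 :], below):
                stats[f] = v
            for f in ["target"] + feats:
                rows.append((f, t, stats[f], 0.5))
        suite = pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
        ranks = within_dataset_rank(suite)
        assert ranks["target"] == 2.0

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(31)
        feats = [f"f{i}" for i in range(6)]
        tests = list(assessment.REGRESSION_TESTS) + list(assessment.CLASSIFICATION_TESTS)
        rows = []
        table = {}
        for t in tests:
            vals = rng.normal(size=6)
            table[t] = vals
            for f, v in zip(feats, vals):
                rows.append((f, t, v, 0.5))
        suite = pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
        ranks = within_dataset_rank(suite)
        # oracle: independent argsort per test
        per_feat = {f: [] for f in feats}
        for t in tests:
            key = np.abs(table[t]) if t not in assessment.CLASSIFICATION_TESTS else table[t]
            order = np.argsort(-key)
            for pos, fi in enumerate(order, start=1):
                per_feat[feats[fi]].append(pos)
        for f in feats:
            assert ranks[f] == np.median(per_feat[f])

    def test_rank_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        feats = [f"f{i}" for i in range(5)]
        rows = []
        for t in assessment.REGRESSION_TESTS:
            vals = rng.random(5)
            for f, v in zip(feats, vals):
                rows.append((f, t, v, 0.5))
        suite = pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
        r1 = within_dataset_rank(suite)
        suite2 = suite.copy()
        suite2.loc[suite2["test"] == "pearson", "statistic"] = (
            suite2.loc[suite2["test"] == "pearson", "statistic"] ** 3
        )
        r2 = within_dataset_rank(suite2)
        pd.testing.assert_series_equal(r1, r2)

    def test_comprehensive_single_dataset_identity(self):
        r = pd.Series({"a": 1.0, "b": 2.0})
        comp = comprehensive_rank({"d1": r})
        pd.testing.assert_series_equal(
            comp["comprehensive_rank"], r.rename("comprehensive_rank")
        )

    def test_comprehensive_median_across_datasets(self):
        ranks = {
            "d1": pd.Series({"f": 3.0}),
            "d2": pd.Series({"f": 5.0}),
            "d3": pd.Series({"f": 7.0}),
        }
        comp = comprehensive_rank(ranks)
        assert comp.loc["f", "comprehensive_rank"] == 5.0


class TestSubsampleRobustness:
    def test_full_fraction_zero_sd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = subsample_robustness(x, y, n_rep=10, frac=1.0, seed=1)
        np.testing.assert_allclose(res["sd"], 0.0, atol=1e-12)

    def test_identity_feature_mean_one_sd_zero(self):
        x = np.arange(50, dtype=float)
        res = subsample_robustness(x, x, n_rep=20, frac=0.8, seed=2)
        assert res.loc["spearman", "mean"] == pytest.approx(1.0)
        assert res.loc["spearman", "sd"] == pytest.approx(0.0)

    def test_subsample_mean_consistent_with_full_data(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = 0.5 * x + rng.normal(size=400)
        res = subsample_robustness(x, y, n_rep=100, frac=0.8, seed=4)
        full = spearmanr(x, y).statistic
        assert abs(res.loc["spearman", "mean"] - full) < 3 * max(
            res.loc["spearman", "sd"], 1e-3
        )


class TestShuffledMeanControl:
    def test_pool_equal_to_cell_set_p_near_one(self):
        rng = np.random.default_rng(6)
        cell = pd.DataFrame(rng.integers(0, 2, (100, 4)).astype(float))
        act = pd.Series(rng.normal(size=100))
        res = shuffled_mean_control(cell, cell, act, n_draws=50, seed=0)
        assert res["empirical_p"] == pytest.approx(1.0)

    def test_planted_cell_signal_low_p(self):
        rng = np.random.default_rng(7)
        n = 500
        act = rng.normal(size=n)
        cell = pd.DataFrame(
            {f"c{i}": (act + rng.normal(0, 0.5, n) > 0).astype(float) for i in range(4)}
        )
        pool = pd.DataFrame(
            {f"p{i}": rng.integers(0, 2, n).astype(float) for i in range(30)}
        )
        res = shuffled_mean_control(cell, pool, pd.Series(act), n_draws=100, seed=1)
        assert res["empirical_p"] <= 0.05

    def test_draws_seed_reproducible(self):
        rng = np.random.default_rng(8)
        cell = pd.DataFrame(rng.integers(0, 2, (50, 3)).astype(float))
        pool = pd.DataFrame(rng.integers(0, 2, (50, 10)).astype(float))
        act = pd.Series(rng.normal(size=50))
        r1 = shuffled_mean_control(cell, pool, act, n_draws=20, seed=5)
        r2 = shuffled_mean_control(cell, pool, act, n_draws=20, seed=5)
        assert r1 == r2

    def test_pool_smaller_than_cell_set_rejected(self):
        cell = pd.DataFrame(np.ones((20, 5)))
        pool = pd.DataFrame(np.ones((20, 3)))
        with pytest.raises(ValueError, match="pool"):
            shuffled_mean_control(cell, pool, pd.Series(np.arange(20.0)))


class TestFeatureTestSuite:
    def test_q_values_within_each_test(self):
        rng = np.random.default_rng(9)
        features = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = pd.Series(features["a"] + rng.normal(0, 0.5, 60))
        labels = pd.Series((y > y.median()).astype(int))
        suite = feature_test_suite(features, y, labels)
        assert set(suite["test"]) == set(assessment.REGRESSION_TESTS) | set(
            assessment.CLASSIFICATION_TESTS
        )
        from mprameta.quantify import bh_adjust

        for t, grp in suite.groupby("test"):
            np.testing.assert_allclose(grp["q"], bh_adjust(grp["p"].to_numpy()))
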