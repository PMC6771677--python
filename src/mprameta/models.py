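"""Supervised and cross-dataset prediction of MPRA output.

Regression of quantitative activity uses a four-member ensemble — an
elastic-net linear model (features standardized, L1/L2 mixing 0.5), a random
forest, extremely randomized trees, and gradient-boosted trees — whose
prediction is the arithmetic mean of the members. Classification of
active/inactive uses a random-forest + extra-trees pair averaging predicted
probabilities. A shuffle-null model with identical composition permutes only
the training targets, quantifying how far the real ensembles are from
chance.

Evaluation is 10-fold: region ids are deterministically round-robined into
10 sections by lexicographic order, so datasets sharing regions are split
consistently. The cross-dataset mode trains on nine sections of one dataset
and tests on the held-out section of another, removing from the training
rows any region that matches a test-fold region by id or overlaps it
genomically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .assessment import classification_tests, regression_tests

__all__ = [
    "ModelSpec",
    "RegressionEnsemble",
    "ClassificationEnsemble",
    "make_splits",
    "train_regression_ensemble",
    "train_classification_ensemble",
    "shuffle_null",
    "cross_validate",
    "cross_dataset_evaluate",
]


@dataclass(frozen=True)
class ModelSpec:
    """Ensemble composition; the prediction is always the member mean."""

    task: str = "regression"  # or "classification"
    n_estimators: int = 1000
    elastic_net_mixing: float = 0.5
    seed: int = 0
    members: tuple[str, ...] = ()

    def member_list(self) -> tuple[str, ...]:
        if self.members:
            return self.members
        if self.task == "regression":
            return ("elastic_net", "random_forest", "extra_trees", "gradient_boosting")
        return ("random_forest", "extra_trees")


def _build_member(name: str, spec: ModelSpec, classifier: bool):
    n, s = spec.n_estimators, spec.seed
    if classifier:
        builders = {
            "random_forest": lambda: RandomForestClassifier(n_estimators=n, random_state=s, n_jobs=1),
            "extra_trees": lambda: ExtraTreesClassifier(n_estimators=n, random_state=s + 1, n_jobs=1),
        }
    else:
        builders = {
            "elastic_net": lambda: make_pipeline(
                StandardScaler(), ElasticNet(l1_ratio=spec.elastic_net_mixing, random_state=s)
            ),
            "random_forest": lambda: RandomForestRegressor(n_estimators=n, random_state=s, n_jobs=1),
            "extra_trees": lambda: ExtraTreesRegressor(n_estimators=n, random_state=s + 1, n_jobs=1),
            "gradient_boosting": lambda: GradientBoostingRegressor(n_estimators=n, random_state=s + 2),
        }
    if name not in builders:
        raise ValueError(f"unknown member {name!r} for this task")
    return builders[name]()


class RegressionEnsemble:
    """Mean of the fitted member regressors' predictions."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.members = {
            name: _build_member(name, spec, classifier=False)
            for name in spec.member_list()
        }

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "RegressionEnsemble":
        yv = np.asarray(y, float)
        if len(np.unique(yv)) < 2:
            raise ValueError("constant training target")
        for m in self.members.values():
            m.fit(X, yv)
        return self

    def member_predictions(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({n: m.predict(X) for n, m in self.members.items()})

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.member_predictions(X).mean(axis=1).to_numpy()


class ClassificationEnsemble:
    """Mean of the fitted member classifiers' positive-class probabilities."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.members = {
            name: _build_member(name, spec, classifier=True)
            for name in spec.member_list()
        }

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "ClassificationEnsemble":
        yv = np.asarray(y, int)
        counts = pd.Series(yv).value_counts()
        if len(counts) < 2:
            raise ValueError("single-class training labels")
        for m in self.members.values():
            m.fit(X, yv)
        return self

    def member_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for name, m in self.members.items():
            proba = m.predict_proba(X)
            pos = list(m.classes_).index(1)
            out[name] = proba[:, pos]
        return pd.DataFrame(out)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.member_probabilities(X).mean(axis=1).to_numpy()


def make_splits(
    region_ids,
    paired_plan: pd.Series | None = None,
    n_sections: int = 10,
) -> pd.Series:
    """Deterministic round-robin assignment of region ids to sections.

    Ids are sorted lexicographically and assigned section ``i mod
    n_sections``; the same id set yields the same plan regardless of input
    order. Ids present in ``paired_plan`` (a previously built plan for a
    dataset sharing regions) inherit their partner's section.
    """
    ids = list(region_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids")
    if len(ids) < n_sections:
        raise ValueError(f"need >= {n_sections} regions, got {len(ids)}")
    plan = pd.Series(
        {rid: i % n_sections for i, rid in enumerate(sorted(ids))},
        name="section",
        dtype=int,
    )
    if paired_plan is not None:
        shared = plan.index.intersection(paired_plan.index)
        plan.loc[shared] = paired_plan.loc[shared].astype(int)
    return plan.loc[sorted(ids)]


def train_regression_ensemble(X: pd.DataFrame, y: pd.Series, spec: ModelSpec) -> RegressionEnsemble:
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return RegressionEnsemble(spec).fit(X, y)


def train_classification_ensemble(X: pd.DataFrame, y: pd.Series, spec: ModelSpec) -> ClassificationEnsemble:
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return ClassificationEnsemble(spec).fit(X, y)


def shuffle_null(X: pd.DataFrame, y: pd.Series, spec: ModelSpec, seed: int = 0):
    """Same ensemble composition, trained on permuted training targets."""
    rng = np.random.default_rng(seed)
    y_perm = pd.Series(rng.permutation(np.asarray(y)), index=y.index, name=y.name)
    if spec.task == "regression":
        return train_regression_ensemble(X, y_perm, spec)
    return train_classification_ensemble(X, y_perm, spec)


def _fold_stats(task: str, pred: np.ndarray, target: np.ndarray) -> pd.Series:
    if task == "regression":
        return regression_tests(pred, target)["statistic"]
    return classification_tests(pred, target)["statistic"]


def cross_validate(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ModelSpec,
    plan: pd.Series | None = None,
    shuffled: bool = False,
    shuffle_seed: int = 0,
) -> dict:
    """10-fold cross-validation within one dataset.

    Returns {"folds": long frame (fold, test, statistic),
    "aggregate": per-test mean and sd over folds,
    "predictions": per-region held-out prediction}.
    Classification folds whose test labels are single-class are skipped with
    a diagnostic entry rather than failing.
    """
    if plan is None:
        plan = make_splits(X.index)
    plan = plan.loc[X.index]
    rows = []
    preds = pd.Series(np.nan, index=X.index, name="prediction")
    skipped = []
    for fold in sorted(plan.unique()):
        test_mask = (plan == fold).to_numpy()
        X_tr, y_tr = X[~test_mask], y[~test_mask]
        X_te, y_te = X[test_mask], y[test_mask]
        if spec.task == "classification" and pd.Series(y_te).nunique() < 2:
            skipped.append(int(fold))
            continue
        if shuffled:
            model = shuffle_null(X_tr, y_tr, spec, seed=shuffle_seed + fold)
        elif spec.task == "regression":
            model = train_regression_ensemble(X_tr, y_tr, spec)
        else:
            model = train_classification_ensemble(X_tr, y_tr, spec)
        p = model.predict(X_te) if spec.task == "regression" else model.predict_proba(X_te)
        preds[test_mask] = p
        for test, val in _fold_stats(spec.task, p, np.asarray(y_te)).items():
            rows.append((int(fold), test, float(val)))
    folds = pd.DataFrame(rows, columns=["fold", "test", "statistic"])
    agg = folds.groupby("test")["statistic"].agg(["mean", "std"]).rename(
        columns={"std": "sd"}
    )
    return {"folds": folds, "aggregate": agg, "predictions": preds, "skipped_folds": skipped}


def _overlapping_ids(
    train_intervals: pd.DataFrame, test_intervals: pd.DataFrame
) -> set[str]:
    """Train region ids whose interval shares >= 1 bp with any test interval."""
    out: set[str] = set()
    for chrom, test_grp in test_intervals.groupby("chrom"):
        tr = train_intervals[train_intervals["chrom"] == chrom]
        for rid, row in tr.iterrows():
            if ((test_grp["start"] < row["end"]) & (test_grp["end"] > row["start"])).any():
                out.add(rid)
    return out


def cross_dataset_evaluate(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    spec: ModelSpec,
    plan: pd.Series | None = None,
    intervals_train: pd.DataFrame | None = None,
    intervals_test: pd.DataFrame | None = None,
) -> dict:
    """Train on nine sections of one dataset, test on the held-out section of another.

    The fold plan is built over the union of region ids so shared regions get
    consistent sections. Before fitting each fold, training rows whose region
    id appears in the test fold — or whose genomic interval overlaps a
    test-fold region, when interval frames (indexed by region id with
    chrom/start/end) are given — are removed.
    """
    shared_cols = X_train.columns.intersection(X_test.columns)
    if len(shared_cols) == 0:
        raise ValueError("train and test datasets share no features")
    X_train, X_test = X_train[shared_cols], X_test[shared_cols]
    if plan is None:
        plan = make_splits(set(X_train.index) | set(X_test.index))
    test_plan = plan.loc[X_test.index]
    rows = []
    preds = pd.Series(np.nan, index=X_test.index, name="prediction")
    skipped = []
    for fold in sorted(test_plan.unique()):
        te_mask = (test_plan == fold).to_numpy()
        te_ids = set(X_test.index[te_mask])
        tr_plan = plan.loc[X_train.index]
        keep = (~tr_plan.index.isin(te_ids)) & (tr_plan != fold).to_numpy()
        if intervals_train is not None and intervals_test is not None:
            olap = _overlapping_ids(
                intervals_train.loc[X_train.index[keep]],
                intervals_test.loc[sorted(te_ids)],
            )
            keep = keep & ~tr_plan.index.isin(olap)
        X_tr, y_tr = X_train[keep], y_train[keep]
        y_te = y_test[te_mask]
        if spec.task == "classification" and pd.Series(y_te).nunique() < 2:
            skipped.append(int(fold))
            continue
        if spec.task == "regression":
            model = train_regression_ensemble(X_tr, y_tr, spec)
            p = model.predict(X_test[te_mask])
        else:
            model = train_classification_ensemble(X_tr, y_tr, spec)
            p = model.predict_proba(X_test[te_mask])
        preds[te_mask] = p
        for test, val in _fold_stats(spec.task, p, np.asarray(y_te)).items():
            rows.append((int(fold), test, float(val)))
    folds = pd.DataFrame(rows, columns=["fold", "test", "statistic"])
    agg = folds.groupby("test")["statistic"].agg(["mean", "std"]).rename(
        columns={"std": "sd"}
    )
    return {"folds": folds, "aggregate": agg, "predictions": preds, "skipped_folds": skipped}
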