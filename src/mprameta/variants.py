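"""Saturation-mutagenesis variant-effect prediction.

Each single-nucleotide variant is represented by the difference between the
variant and wild-type sequence-intrinsic feature vectors (k-mer presence,
composition, motif-scan summaries, and any pluggable per-sequence score
providers); positional annotations are identical between the alleles and
carry no signal, so only features that can differ are used. Concatenation of
the two allele vectors is available as an alternative representation.

Discrete effects (-1 / 0 / +1) are predicted with a ten-member tree ensemble
(five random forests + five extra-trees classifiers), one model per element
class. Continuous effects are predicted per element (the stronger strategy)
or per element class, with element-class-specific member rosters: promoters
use one random forest + one extra-trees + one gradient-boosting regressor,
enhancers five random forests + five extra-trees regressors. All tree
members use sqrt-of-features splits and 1,000 estimators by default, with
member seeds derived as base seed + member index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import roc_auc_score

from .featurize import sequence_feature_block

__all__ = [
    "VariantFeatureConfig",
    "featurize_variant",
    "variant_feature_table",
    "DiscreteVariantEnsemble",
    "train_discrete",
    "ContinuousVariantEnsemble",
    "train_continuous",
    "evaluate_variants",
    "cross_element_evaluate",
]


@dataclass(frozen=True)
class VariantFeatureConfig:
    k: int = 5
    pwms: tuple = ()
    motif_p_threshold: float = 1e-4
    representation: str = "difference"  # or "concatenation"
    score_providers: dict | None = None


def _seq_features(seq: str, cfg: VariantFeatureConfig) -> pd.Series:
    block = sequence_feature_block(
        {"x": seq},
        pwms=list(cfg.pwms) or None,
        k=cfg.k,
        p_threshold=cfg.motif_p_threshold,
        score_providers=cfg.score_providers,
    )
    return block.loc["x"]


def featurize_variant(
    wt_seq: str,
    position: int,
    ref: str,
    alt: str,
    config: VariantFeatureConfig | None = None,
) -> pd.Series:
    """Feature representation of a single-nucleotide variant.

    Builds the variant sequence, computes sequence-intrinsic features for
    both alleles, and returns either their difference (variant minus
    wild-type; zero vector when alt == ref, antisymmetric under swapping the
    alleles) or their concatenation.
    """
    config = config or VariantFeatureConfig()
    if not 0 <= position < len(wt_seq):
        raise ValueError(f"position {position} outside the element (length {len(wt_seq)})")
    if wt_seq[position] != ref:
        raise ValueError(
            f"ref mismatch at position {position}: expected {ref!r}, "
            f"sequence has {wt_seq[position]!r}"
        )
    var_seq = wt_seq[:position] + alt + wt_seq[position + 1 :]
    wt = _seq_features(wt_seq, config)
    var = _seq_features(var_seq, config)
    if config.representation == "difference":
        return (var - wt).rename("diff")
    if config.representation == "concatenation":
        wt_part = wt.rename(lambda c: f"wt_{c}")
        var_part = var.rename(lambda c: f"var_{c}")
        return pd.concat([var_part, wt_part]).rename("concat")
    raise ValueError(f"unknown representation {config.representation!r}")


def variant_feature_table(
    variants: pd.DataFrame,
    element_seqs: dict[str, str],
    config: VariantFeatureConfig | None = None,
) -> pd.DataFrame:
    """Featurize every row of a variant table (element_id, position, ref, alt).

    Wild-type features are computed once per element and reused across its
    variants. Returns a frame aligned with ``variants.index``.
    """
    config = config or VariantFeatureConfig()
    wt_cache = {
        eid: _seq_features(seq, config) for eid, seq in element_seqs.items()
    }
    rows = []
    for _, row in variants.iterrows():
        eid = row["element_id"]
        wt_seq = element_seqs[eid]
        pos, ref, alt = int(row["position"]), row["ref"], row["alt"]
        if wt_seq[pos] != ref:
            raise ValueError(
                f"ref mismatch in element {eid!r} at position {pos}: "
                f"expected {ref!r}, sequence has {wt_seq[pos]!r}"
            )
        var_seq = wt_seq[:pos] + alt + wt_seq[pos + 1 :]
        var = _seq_features(var_seq, config)
        wt = wt_cache[eid]
        if config.representation == "difference":
            rows.append(var - wt)
        else:
            rows.append(
                pd.concat(
                    [var.rename(lambda c: f"var_{c}"), wt.rename(lambda c: f"wt_{c}")]
                )
            )
    return pd.DataFrame(rows, index=variants.index)


class DiscreteVariantEnsemble:
    """5 RF + 5 ET multiclass classifiers; class by mean probability.

    Probability ties break toward the lowest class.
    """

    def __init__(self, n_estimators: int = 1000, seed: int = 0):
        self.members = []
        for i in range(5):
            self.members.append(
                RandomForestClassifier(
                    n_estimators=n_estimators, max_features="sqrt",
                    random_state=seed + i, n_jobs=1,
                )
            )
        for i in range(5):
            self.members.append(
                ExtraTreesClassifier(
                    n_estimators=n_estimators, max_features="sqrt",
                    random_state=seed + 5 + i, n_jobs=1,
                )
            )

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "DiscreteVariantEnsemble":
        yv = np.asarray(y, int)
        if len(np.unique(yv)) < 2:
            raise ValueError("training labels contain a single class")
        for m in self.members:
            m.fit(X, yv)
        self.classes_ = np.array(sorted(np.unique(yv)))
        return self

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        acc = np.zeros((len(X), len(self.classes_)))
        for m in self.members:
            proba = m.predict_proba(X)
            for j, c in enumerate(m.classes_):
                acc[:, list(self.classes_).index(c)] += proba[:, j]
        return pd.DataFrame(acc / len(self.members), columns=self.classes_, index=X.index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax with lowest class winning ties (classes_ sorted ascending)
        return self.classes_[np.argmax(proba.to_numpy(), axis=1)]


def train_discrete(
    X: pd.DataFrame, labels: pd.Series, n_estimators: int = 1000, seed: int = 0
) -> DiscreteVariantEnsemble:
    return DiscreteVariantEnsemble(n_estimators=n_estimators, seed=seed).fit(X, labels)


_ROSTERS = {
    "promoter": [
        ("rf", RandomForestRegressor, 1),
        ("et", ExtraTreesRegressor, 1),
        ("gb", GradientBoostingRegressor, 1),
    ],
    "enhancer": [
        ("rf", RandomForestRegressor, 5),
        ("et", ExtraTreesRegressor, 5),
    ],
}


class ContinuousVariantEnsemble:
    """Element-class-specific regressor roster; prediction is the member mean."""

    def __init__(self, element_class: str, n_estimators: int = 1000, seed: int = 0):
        if element_class not in _ROSTERS:
            raise ValueError(f"unknown element class {element_class!r}")
        self.element_class = element_class
        self.members = []
        i = 0
        for _, cls, count in _ROSTERS[element_class]:
            for _ in range(count):
                kwargs = {"n_estimators": n_estimators, "random_state": seed + i}
                if cls is not GradientBoostingRegressor:
                    kwargs.update(max_features="sqrt", n_jobs=1)
                self.members.append(cls(**kwargs))
                i += 1

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "ContinuousVariantEnsemble":
        for m in self.members:
            m.fit(X, np.asarray(y, float))
        return self

    def member_predictions(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({i: m.predict(X) for i, m in enumerate(self.members)})

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.member_predictions(X).mean(axis=1).to_numpy()


def train_continuous(
    variants: pd.DataFrame,
    features: pd.DataFrame,
    scope: str = "per_element",
    n_estimators: int = 1000,
    seed: int = 0,
    min_train: int = 50,
) -> dict[str, ContinuousVariantEnsemble]:
    """Fit continuous-effect regressors at per-element or per-class scope.

    Returns a dict keyed by element_id (per_element) or element_class
    (per_class); groups with fewer than ``min_train`` training variants are
    absent from it.
    """
    if scope not in ("per_element", "per_class"):
        raise ValueError(f"unknown scope {scope!r}")
    key = "element_id" if scope == "per_element" else "element_class"
    models: dict[str, ContinuousVariantEnsemble] = {}
    for name, grp in variants.groupby(key):
        if len(grp) < min_train:
            continue
        element_class = grp["element_class"].iloc[0]
        model = ContinuousVariantEnsemble(
            element_class, n_estimators=n_estimators, seed=seed
        )
        model.fit(features.loc[grp.index], grp["continuous_effect"])
        models[name] = model
    if not models:
        raise ValueError(f"no group reached the minimum of {min_train} training variants")
    return models


def _safe_pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return 0.0  # flagged-degenerate
    return float(stats.pearsonr(a, b)[0])


def evaluate_variants(
    pred_labels: np.ndarray | None,
    pred_continuous: np.ndarray | None,
    truth: pd.DataFrame,
) -> dict[str, float]:
    """The five variant-prediction statistics.

    label_pearson — Pearson of the predicted discrete labels (-1/0/+1)
    against the measured continuous effects; continuous_pearson/spearman —
    correlation of continuous predictions with measured effects; and three
    one-vs-rest/one-vs-one AUROCs of the discretized task. AUROCs whose
    positive or negative class is absent are reported as NaN.
    """
    out: dict[str, float] = {}
    effects = truth["continuous_effect"].to_numpy(float)
    classes = truth["discrete_class"].to_numpy(int)
    if pred_labels is not None:
        out["label_pearson"] = _safe_pearson(pred_labels, effects)
        score = np.asarray(pred_labels, float)
        pairs = {
            "auroc_pos_vs_neg": (classes == 1, classes == -1),
            "auroc_pos_vs_rest": (classes == 1, classes != 1),
            "auroc_neg_vs_rest": (classes == -1, classes != -1),
        }
        for name, (pos, neg) in pairs.items():
            mask = pos | neg
            if pos.sum() == 0 or neg.sum() == 0:
                out[name] = np.nan
                continue
            y = pos[mask].astype(int)
            s = score[mask] if name != "auroc_neg_vs_rest" else -score[mask]
            out[name] = float(roc_auc_score(y, s))
    if pred_continuous is not None:
        pc = np.asarray(pred_continuous, float)
        out["continuous_pearson"] = _safe_pearson(pc, effects)
        if np.all(effects == effects[0]) or np.all(pc == pc[0]):
            out["continuous_spearman"] = 0.0
        else:
            out["continuous_spearman"] = float(stats.spearmanr(pc, effects).statistic)
    return out


def cross_element_evaluate(
    variants: pd.DataFrame,
    features: pd.DataFrame,
    element_class: str,
    n_estimators: int = 100,
    seed: int = 0,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Train-element x test-element matrix of continuous-effect Pearson.

    Off-diagonal (A, B): fit on all of A's variants, evaluate on all of B's.
    Diagonal: within-element ``n_folds``-fold cross-validation Pearson
    (predictions pooled across folds).
    """
    vc = variants[variants["element_class"] == element_class]
    elements = sorted(vc["element_id"].unique())
    if len(elements) < 2:
        raise ValueError("need >= 2 elements in the class")
    mat = pd.DataFrame(np.nan, index=elements, columns=elements)
    for a in elements:
        grp_a = vc[vc["element_id"] == a]
        Xa, ya = features.loc[grp_a.index], grp_a["continuous_effect"]
        model = ContinuousVariantEnsemble(element_class, n_estimators=n_estimators, seed=seed)
        model.fit(Xa, ya)
        for b in elements:
            if b == a:
                continue
            grp_b = vc[vc["element_id"] == b]
            pred = model.predict(features.loc[grp_b.index])
            mat.loc[a, b] = _safe_pearson(pred, grp_b["continuous_effect"])
        # diagonal: pooled 10-fold CV within the element
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(grp_a))
        folds = np.array_split(order, n_folds)
        pooled = np.full(len(grp_a), np.nan)
        for fold in folds:
            mask = np.zeros(len(grp_a), dtype=bool)
            mask[fold] = True
            m = ContinuousVariantEnsemble(element_class, n_estimators=n_estimators, seed=seed)
            m.fit(Xa[~mask], ya[~mask])
            pooled[mask] = m.predict(Xa[mask])
        mat.loc[a, a] = _safe_pearson(pooled, ya)
    return mat
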