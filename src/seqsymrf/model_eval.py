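"""Random-forest training, repeated k-fold evaluation and candidate ranking.

The classifier is a random forest scored by the fraction of trees voting
positive.  Evaluation reports Acc, Spe, Sen, Pre (percentages), Mcc, and
the areas under the ROC and precision-recall curves:

    Acc = (TP + TN) / (TP + TN + FP + FN) * 100%
    Spe = TN / (TN + FP) * 100%
    Sen = TP / (TP + FN) * 100%
    Pre = TP / (TP + FP) * 100%
    Mcc = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP))

A metric whose denominator vanishes is reported as missing (NaN), never 0.

Two cross-validation modes are provided.  ``cross_validate`` evaluates a
fixed design matrix (negatives selected once on the full data).
``cross_validate_pu`` is the strict positive-unlabeled protocol: positives
are folded, and within every fold the reliable negatives for both the
training and the test side are re-selected using only that fold's
training positives, so no information from held-out positives leaks into
negative selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from . import dataset as ds

Pair = tuple[str, str]

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "GridConfig",
    "CVResult",
    "metrics_from_counts",
    "metrics_from_predictions",
    "auroc",
    "auprc",
    "cross_validate",
    "cross_validate_pu",
    "grid_search",
    "train_final",
    "save_model",
    "load_model",
    "predict_scores",
    "rank_candidates",
    "feature_importance",
]

METRIC_NAMES = ("acc", "spe", "sen", "pre", "mcc", "auroc", "auprc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Acc/Spe/Sen/Pre as percentages, Mcc in [-1, 1], areas in [0, 1];
    NaN marks a metric whose denominator was undefined or not computed."""

    acc: float
    spe: float
    sen: float
    pre: float
    mcc: float
    auroc: float = math.nan
    auprc: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Threshold metrics from a confusion matrix (areas are NaN here)."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (c.tp + c.tn) / c.total * 100.0
    spe = c.tn / (c.tn + c.fp) * 100.0 if c.tn + c.fp else math.nan
    sen = c.tp / (c.tp + c.fn) * 100.0 if c.tp + c.fn else math.nan
    pre = c.tp / (c.tp + c.fp) * 100.0 if c.tp + c.fp else math.nan
    denom = (
        (c.tp + c.fn) * (c.tn + c.fn) * (c.tp + c.fp) * (c.tn + c.fp)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else math.nan
    )
    return MetricSet(acc=acc, spe=spe, sen=sen, pre=pre, mcc=mcc)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal area under the ROC (ties contribute 1/2 concordance)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    y = np.asarray(labels)
    if not np.any(y == 1):
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def metrics_from_predictions(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    c = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y_true == 1))),
        tn=int(np.sum((pred == 0) & (y_true == 0))),
        fp=int(np.sum((pred == 1) & (y_true == 0))),
        fn=int(np.sum((pred == 0) & (y_true == 1))),
    )
    base = metrics_from_counts(c)
    both = len(np.unique(y_true)) == 2
    return MetricSet(
        acc=base.acc, spe=base.spe, sen=base.sen, pre=base.pre, mcc=base.mcc,
        auroc=auroc(scores, y_true) if both else math.nan,
        auprc=auprc(scores, y_true) if np.any(y_true == 1) else math.nan,
    )


@dataclass(frozen=True)
class GridConfig:
    """Random-forest search grid: trees 100..1000 step 100; split-feature
    counts 2, 4, 8, 16, 32 plus the sqrt default (22 for 448 features).
    The published optimum is 100 trees with 22 split features."""

    tree_counts: tuple[int, ...] = tuple(range(100, 1001, 100))
    split_feature_counts: tuple[int, ...] = (2, 4, 8, 16, 32)
    include_sqrt_default: bool = True

    def split_counts_for(self, n_features: int) -> tuple[int, ...]:
        counts = [c for c in self.split_feature_counts if c <= n_features]
        if self.include_sqrt_default:
            root = int(round(math.sqrt(n_features)))
            if root not in counts and root <= n_features:
                counts.append(root)
        return tuple(sorted(counts))


@dataclass
class CVResult:
    """Per-fold metric table plus summary statistics."""

    folds: pd.DataFrame  # one row per (repeat, fold), columns = METRIC_NAMES
    trees: int
    split_features: int

    def mean(self) -> MetricSet:
        m = self.folds[list(METRIC_NAMES)].mean()
        return MetricSet(**{k: float(m[k]) for k in METRIC_NAMES})

    def rsd(self) -> dict[str, float]:
        """Relative standard deviation (%) of each metric across folds."""
        out = {}
        for k in METRIC_NAMES:
            mu = self.folds[k].mean()
            out[k] = float(self.folds[k].std(ddof=1) / mu * 100) if mu else math.nan
        return out

    def summary(self) -> pd.DataFrame:
        mean = self.mean().as_dict()
        rsd = self.rsd()
        return pd.DataFrame(
            {"metric": list(METRIC_NAMES),
             "mean": [mean[k] for k in METRIC_NAMES],
             "rsd_percent": [rsd[k] for k in METRIC_NAMES]}
        )


def _forest(trees: int, split_features: int | None, n_features: int, seed: int
            ) -> RandomForestClassifier:
    if split_features is None:
        mf: int | str = "sqrt"
    else:
        mf = min(split_features, n_features)
    return RandomForestClassifier(
        n_estimators=trees, max_features=mf, random_state=seed, n_jobs=1
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    repeats: int = 10,
    trees: int = 100,
    split_features: int | None = 22,
    seed: int = 0,
) -> CVResult:
    """Seeded stratified k-fold CV, repeated, on a fixed design matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation requires both classes")
    splitter = RepeatedStratifiedKFold(
        n_splits=k, n_repeats=repeats, random_state=seed
    )
    rows = []
    for fold_i, (tr, te) in enumerate(splitter.split(X, y)):
        clf = _forest(trees, split_features, X.shape[1], seed)
        clf.fit(X[tr], y[tr])
        scores = clf.predict_proba(X[te])[:, 1]
        m = metrics_from_predictions(y[te], scores)
        rows.append({"repeat": fold_i // k, "fold": fold_i % k, **m.as_dict()})
    return CVResult(folds=pd.DataFrame(rows), trees=trees,
                    split_features=split_features or 0)


def cross_validate_pu(
    positives: Sequence[Pair],
    universe: Sequence[Pair],
    mirna_features: pd.DataFrame,
    disease_features: pd.DataFrame,
    multiplier: float = 1.5,
    ratio: int = 1,
    k: int = 5,
    repeats: int = 10,
    trees: int = 100,
    split_features: int | None = 22,
    seed: int = 0,
    selection: str = "reliable",
) -> CVResult:
    """Strict per-fold positive-unlabeled cross-validation.

    Positives are folded; in each fold the centroid and AED threshold are
    computed from the training positives only, training negatives (ratio x
    train positives) and test negatives (1:1 with test positives) are
    drawn disjointly from the reliable candidates, and the forest is
    evaluated on the held-out positives plus their fresh negatives.

    ``selection`` chooses the negative-mining strategy: ``"reliable"``
    (centroid/AED thresholding, the method's contribution) or
    ``"random"`` (uniform draws from the unlabeled set, the baseline
    strategy it is compared against).  Random selection has no centroid
    bias, so it is also the artifact-free readout of how learnable a
    planted signal is.
    """
    if selection not in ("reliable", "random"):
        raise ValueError("selection must be 'reliable' or 'random'")
    positives = list(positives)
    rng = np.random.default_rng(seed)
    rows = []
    n_features = mirna_features.shape[1] + disease_features.shape[1]
    for rep in range(repeats):
        order = rng.permutation(len(positives))
        folds = np.array_split(order, k)
        for fold_id, test_idx in enumerate(folds):
            test_pos = [positives[i] for i in test_idx]
            train_pos = [positives[i] for i in order if i not in set(test_idx)]
            centroid = ds.positive_centroid(
                train_pos, mirna_features, disease_features
            )
            fold_seed = int(rng.integers(0, 2**31 - 1))
            n_neg = ratio * len(train_pos) + len(test_pos)
            if selection == "reliable":
                sel = ds.select_reliable_negatives(
                    universe, mirna_features, disease_features, centroid,
                    multiplier=multiplier, n_select=n_neg, seed=fold_seed,
                )
                picked = sel.selected
            else:
                pick_rng = np.random.default_rng(fold_seed)
                idx = pick_rng.choice(len(universe), size=n_neg, replace=False)
                picked = [universe[i] for i in idx]
            train_neg = picked[: ratio * len(train_pos)]
            test_neg = picked[ratio * len(train_pos):]
            Xtr = ds.pair_features(
                train_pos + list(train_neg), mirna_features, disease_features
            )
            ytr = np.r_[np.ones(len(train_pos)), np.zeros(len(train_neg))]
            Xte = ds.pair_features(
                test_pos + list(test_neg), mirna_features, disease_features
            )
            yte = np.r_[np.ones(len(test_pos)), np.zeros(len(test_neg))]
            clf = _forest(trees, split_features, n_features, fold_seed)
            clf.fit(Xtr, ytr.astype(int))
            scores = clf.predict_proba(Xte)[:, 1]
            m = metrics_from_predictions(yte, scores)
            rows.append({"repeat": rep, "fold": fold_id, **m.as_dict()})
    return CVResult(folds=pd.DataFrame(rows), trees=trees,
                    split_features=split_features or 0)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: GridConfig | None = None,
    k: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Evaluate every (trees, split features) cell and pick a configuration.

    The chosen cell is the smallest (fewest trees, then fewest split
    features) whose mean accuracy is within one standard deviation of the
    best cell's mean — the economy rule that favours compact forests when
    performance has plateaued.
    """
    grid = grid or GridConfig()
    X = np.asarray(X, dtype=float)
    split_counts = grid.split_counts_for(X.shape[1])
    rows = []
    for trees in grid.tree_counts:
        for mtry in split_counts:
            res = cross_validate(
                X, y, k=k, repeats=repeats, trees=trees,
                split_features=mtry, seed=seed,
            )
            mean = res.mean()
            rows.append({
                "trees": trees, "split_features": mtry,
                "acc_sd": float(res.folds["acc"].std(ddof=1)),
                **mean.as_dict(),
            })
    table = pd.DataFrame(rows)
    best = table.loc[table["acc"].idxmax()]
    floor = best["acc"] - best["acc_sd"]
    ok = table[table["acc"] >= floor].sort_values(["trees", "split_features"])
    chosen = ok.iloc[0]
    return table, (int(chosen["trees"]), int(chosen["split_features"]))


@dataclass
class FittedModel:
    """A trained forest plus the feature-name contract used to fit it."""

    forest: RandomForestClassifier
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.forest.n_features_in_


def train_final(
    X: np.ndarray,
    y: np.ndarray,
    trees: int = 100,
    split_features: int | None = 22,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> FittedModel:
    """Fit the final forest (published defaults: 100 trees, 22 split
    features) on the full training matrix."""
    X = np.asarray(X, dtype=float)
    clf = _forest(trees, split_features, X.shape[1], seed)
    clf.fit(X, np.asarray(y).astype(int))
    return FittedModel(
        forest=clf,
        feature_names=list(feature_names) if feature_names is not None else [],
    )


def save_model(model: FittedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> FittedModel:
    model = joblib.load(path)
    if not isinstance(model, FittedModel):
        raise TypeError(f"{path} does not contain a FittedModel")
    return model


def predict_scores(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Association scores: the fraction of trees voting positive."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features}, "
            f"got {X.shape[1]}"
        )
    return model.forest.predict_proba(X)[:, 1]


def rank_candidates(
    query_id: str,
    query_kind: str,
    positives: Sequence[Pair],
    mirna_features: pd.DataFrame,
    disease_features: pd.DataFrame,
    multiplier: float = 1.5,
    ratio: int = 1,
    trees: int = 100,
    split_features: int | None = 22,
    seed: int = 0,
    top: int | None = None,
) -> list[tuple[str, float]]:
    """Leave-query-out candidate ranking (the case-study protocol).

    All pairs touching the query disease (or miRNA) are removed, the model
    is retrained from scratch on the remaining positives with freshly
    selected reliable negatives, and every candidate partner is scored for
    the query.  Returns (candidate, score) in descending score order with
    stable id tie-breaks; ``top`` truncates the list (a ``top`` larger
    than the candidate count returns everything).
    """
    if query_kind not in ("disease", "mirna"):
        raise ValueError("query_kind must be 'disease' or 'mirna'")
    table = disease_features if query_kind == "disease" else mirna_features
    if query_id not in table.index:
        raise KeyError(f"{query_kind} {query_id!r} not in the feature table")

    col = 1 if query_kind == "disease" else 0
    kept_pos = [p for p in positives if p[col] != query_id]
    if not kept_pos:
        raise ValueError("no positives remain after removing the query")
    kept_pos_set = set(kept_pos)
    universe = [
        (m, d)
        for m in mirna_features.index
        for d in disease_features.index
        if (m, d) not in kept_pos_set and m != query_id and d != query_id
    ]
    centroid = ds.positive_centroid(kept_pos, mirna_features, disease_features)
    sel = ds.select_reliable_negatives(
        universe, mirna_features, disease_features, centroid,
        multiplier=multiplier, n_select=ratio * len(kept_pos), seed=seed,
    )
    X, y, _ = ds.make_training_set(
        kept_pos, sel.selected, mirna_features, disease_features,
        ratio=ratio, seed=seed,
    )
    model = train_final(
        X, y, trees=trees, split_features=split_features, seed=seed
    )
    if query_kind == "disease":
        candidates = list(mirna_features.index)
        pairs = [(c, query_id) for c in candidates]
    else:
        candidates = list(disease_features.index)
        pairs = [(query_id, c) for c in candidates]
    scores = predict_scores(
        model, ds.pair_features(pairs, mirna_features, disease_features)
    )
    ranked = sorted(zip(candidates, scores), key=lambda cs: (-cs[1], cs[0]))
    return ranked[:top] if top is not None else ranked


def feature_importance(
    model: FittedModel,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance (mean AUROC drop when a feature is
    shuffled), sorted descending."""
    result = permutation_importance(
        model.forest, np.asarray(X, dtype=float), np.asarray(y).astype(int),
        n_repeats=n_repeats, random_state=seed, scoring="roc_auc",
    )
    names = (
        model.feature_names
        if model.feature_names
        else [f"f{i}" for i in range(model.n_features)]
    )
    return (
        pd.DataFrame({
            "feature": names,
            "importance_mean": result.importances_mean,
            "importance_sd": result.importances_std,
        })
        .sort_values("importance_mean", ascending=False)
        .reset_index(drop=True)
    )
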