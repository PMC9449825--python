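"""Participant-grouped cross-validation and feature-importance analysis.

Fold assignment is by participant, never by segment, so no individual
contributes to both the training and the test side of any fold; every
cross-validation run re-asserts this (the leakage guard).  The metric
throughout is the class-weighted F1 score.  Feature importances come
in two flavors: impurity-based (Gini, or gain for boosted trees) read
from tree-family models, and permutation importance computed on
held-out fold data; either can be re-grouped by device location and
sensor channel via the per-column metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

from . import classifiers
from .classifiers import ModelSpec, TrainedModel
from .featurizer import FeatureMatrix, fit_standardizer
from .segmenter import SegmentSet
from .sensordata import CHANNELS, LOCATIONS

__all__ = [
    "LeakageError",
    "FoldAssignment",
    "CvResult",
    "ImportanceTable",
    "grouped_folds",
    "weighted_f1",
    "cross_validate",
    "gini_importance",
    "permutation_importance",
    "cv_permutation_importance",
    "group_importance",
]

_TREE_FAMILIES = {"decision_tree", "random_forest", "xgboost"}


class LeakageError(Exception):
    """A fold assignment put one participant on both sides of a fold."""


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of participant groups into k folds."""

    k: int
    group_to_fold: dict[str, int]

    def test_mask(self, groups: np.ndarray, fold: int) -> np.ndarray:
        return np.array([self.group_to_fold[g] == fold for g in groups])

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.group_to_fold.values():
            sizes[f] += 1
        return sizes


def grouped_folds(groups: Sequence[str], k: int, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle of the distinct groups, then round-robin assignment.

    Fold group-counts therefore differ by at most one.
    """
    unique = list(dict.fromkeys(groups))  # stable first-appearance order
    if len(unique) < k:
        raise ValueError(f"need at least k={k} distinct groups, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    return FoldAssignment(k=k, group_to_fold={g: i % k for i, g in enumerate(order)})


def weighted_f1(y_true, y_pred) -> float:
    """Per-class F1 averaged with weights equal to class support in y_true.

    Classes absent from y_true are ignored; a class with no true and no
    predicted positives contributes an F1 of 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("weighted_f1 of empty input is undefined")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return float(
        _sk_f1(y_true, y_pred, average="weighted", zero_division=0,
               labels=np.unique(y_true))
    )


def _assert_no_leakage(train_groups: np.ndarray, test_groups: np.ndarray) -> None:
    shared = set(train_groups) & set(test_groups)
    if shared:
        raise LeakageError(
            f"participants present in both train and test: {sorted(shared)}"
        )


@dataclass
class CvResult:
    """Per-fold class-weighted F1 scores and confusion matrices."""

    fold_scores: list[float]
    confusion: pd.DataFrame  # pooled, rows = true class, columns = predicted
    fold_confusions: list[pd.DataFrame] = field(default_factory=list, repr=False)
    fold_assignment: FoldAssignment | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_scores))

    def summary(self) -> dict:
        return {"mean_f1": self.mean, "sd_f1": self.sd,
                "fold_f1": list(map(float, self.fold_scores))}


def _standardize_segments(train: np.ndarray, test: np.ndarray):
    # per-channel z-scoring fitted on the training fold
    mean = train.mean(axis=(0, 1), keepdims=True)
    sd = train.std(axis=(0, 1), keepdims=True)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (train - mean) / sd, (test - mean) / sd


def cross_validate(
    spec: ModelSpec,
    data: FeatureMatrix | SegmentSet,
    labels: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    k: int = 6,
    seed: int = 0,
    folds: FoldAssignment | np.ndarray | None = None,
    standardize: str = "per_fold",
) -> CvResult:
    """Participant-grouped k-fold cross-validation of one model spec.

    For engineered-feature families the standardizer is fitted on each
    training fold only (``standardize="per_fold"``, the default);
    ``"global"`` fits it once on all rows, a deliberately leaky
    variant kept for fidelity comparisons.  ``folds`` may override the
    seeded round-robin assignment, either as a FoldAssignment or as a
    per-segment fold index array (in which case the leakage guard
    still vets it).
    """
    if standardize not in ("per_fold", "global"):
        raise ValueError(f"unknown standardization mode {standardize!r}")
    labels = np.asarray(labels if labels is not None else data.labels)
    groups = np.asarray(groups if groups is not None else data.groups)
    if labels.shape[0] != groups.shape[0]:
        raise ValueError("labels and groups must have equal length")

    if folds is None:
        folds = grouped_folds(groups, k, seed)
    if isinstance(folds, FoldAssignment):
        k = folds.k
        fold_idx = np.array([folds.group_to_fold[g] for g in groups])
        assignment = folds
    else:
        fold_idx = np.asarray(folds)
        k = int(fold_idx.max()) + 1
        assignment = None

    class_order = np.unique(labels)
    scores: list[float] = []
    fold_confusions: list[pd.DataFrame] = []
    pooled = np.zeros((len(class_order), len(class_order)), dtype=int)
    for fold in range(k):
        test_mask = fold_idx == fold
        train_mask = ~test_mask
        _assert_no_leakage(groups[train_mask], groups[test_mask])
        y_train, y_test = labels[train_mask], labels[test_mask]
        if isinstance(data, SegmentSet):
            x_train, x_test = _standardize_segments(
                data.tensor[train_mask], data.tensor[test_mask]
            )
        else:
            std = fit_standardizer(
                data.matrix if standardize == "global" else data.matrix[train_mask]
            )
            x_train = std.transform(data.matrix[train_mask])
            x_test = std.transform(data.matrix[test_mask])
        try:
            model = classifiers.fit(spec, x_train, y_train)
            y_pred = classifiers.predict(model, x_test)
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        scores.append(weighted_f1(y_test, y_pred))
        cm = _sk_confusion(y_test, y_pred, labels=class_order)
        pooled += cm
        fold_confusions.append(
            pd.DataFrame(cm, index=class_order, columns=class_order)
        )
    return CvResult(
        fold_scores=scores,
        confusion=pd.DataFrame(pooled, index=class_order, columns=class_order),
        fold_confusions=fold_confusions,
        fold_assignment=assignment,
    )


@dataclass
class ImportanceTable:
    """Per-feature importances joined with column provenance."""

    table: pd.DataFrame  # location, channel, axis, feature_name, importance
    method: str  # "gini" | "permutation"
    aggregation: str = "feature"


def _meta_or_default(feature_meta: pd.DataFrame | None, n: int) -> pd.DataFrame:
    if feature_meta is not None:
        return feature_meta.reset_index(drop=True).copy()
    return pd.DataFrame(
        {"location": [""] * n, "channel": [""] * n, "axis": [""] * n,
         "feature_name": [f"f{i}" for i in range(n)]}
    )


def gini_importance(model: TrainedModel, feature_meta: pd.DataFrame | None = None) -> ImportanceTable:
    """Normalized impurity-decrease importances of a tree-family model.

    For the boosted model this is the library's gain-type score, the
    boosting analog of Gini importance.
    """
    if model.spec.family not in _TREE_FAMILIES:
        raise ValueError(
            f"gini importance requires a tree-family model, got {model.spec.family!r}"
        )
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    meta = _meta_or_default(feature_meta, len(imp))
    meta["importance"] = imp
    return ImportanceTable(table=meta, method="gini")


def permutation_importance(
    model: TrainedModel,
    X_val: FeatureMatrix | np.ndarray,
    y_val: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Held-out permutation importance, scored with weighted F1.

    importance(j) = baseline F1 - mean over repeats of the F1 obtained
    with column j randomly permuted.  Negative values indicate columns
    whose permutation helped by chance.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    meta = X_val.feature_meta if isinstance(X_val, FeatureMatrix) else None
    matrix = X_val.matrix if isinstance(X_val, FeatureMatrix) else np.asarray(X_val)
    matrix = matrix.copy()
    y_val = np.asarray(y_val)
    rng = np.random.default_rng(seed)
    baseline = weighted_f1(y_val, classifiers.predict(model, matrix))
    n_rows, n_cols = matrix.shape
    importances = np.empty(n_cols)
    for j in range(n_cols):
        original = matrix[:, j].copy()
        drop = 0.0
        for _ in range(n_repeats):
            matrix[:, j] = original[rng.permutation(n_rows)]
            drop += baseline - weighted_f1(y_val, classifiers.predict(model, matrix))
        matrix[:, j] = original
        importances[j] = drop / n_repeats
    out = _meta_or_default(meta, n_cols)
    out["importance"] = importances
    return ImportanceTable(table=out, method="permutation")


def grouped_permutation_importance(
    model: TrainedModel,
    X_val: FeatureMatrix,
    y_val: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceTable:
    """Permutation importance of whole (location, channel) blocks.

    All feature columns derived from one device/channel pair are
    permuted jointly (same row shuffle), which is the standard remedy
    for the vanishing per-column importances that highly correlated
    engineered features produce.  Returns one row per block.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    meta = X_val.feature_meta
    if "location" not in meta.columns or meta["location"].eq("").all():
        raise ValueError("grouped permutation importance needs location/channel metadata")
    matrix = X_val.matrix.copy()
    y_val = np.asarray(y_val)
    rng = np.random.default_rng(seed)
    baseline = weighted_f1(y_val, classifiers.predict(model, matrix))
    n_rows = matrix.shape[0]
    keys = list(dict.fromkeys(zip(meta["location"], meta["channel"])))
    records = []
    for loc, ch in keys:
        cols = np.flatnonzero((meta["location"] == loc) & (meta["channel"] == ch))
        original = matrix[:, cols].copy()
        drop = 0.0
        for _ in range(n_repeats):
            matrix[:, cols] = original[rng.permutation(n_rows)]
            drop += baseline - weighted_f1(y_val, classifiers.predict(model, matrix))
        matrix[:, cols] = original
        records.append(
            {"location": loc, "channel": ch, "axis": "*", "feature_name": "*",
             "importance": drop / n_repeats}
        )
    return ImportanceTable(
        table=pd.DataFrame(records), method="permutation",
        aggregation="location_channel",
    )


def cv_grouped_permutation_importance(
    spec: ModelSpec,
    features: FeatureMatrix,
    k: int = 6,
    seed: int = 0,
    n_repeats: int = 10,
    n_folds_used: int | None = None,
) -> ImportanceTable:
    """Block permutation importance per held-out fold, fold-averaged."""
    assignment = grouped_folds(features.groups, k, seed)
    fold_idx = np.array([assignment.group_to_fold[g] for g in features.groups])
    use = range(k if n_folds_used is None else min(n_folds_used, k))
    acc: np.ndarray | None = None
    base: pd.DataFrame | None = None
    for fold in use:
        test_mask = fold_idx == fold
        _assert_no_leakage(features.groups[~test_mask], features.groups[test_mask])
        std = fit_standardizer(features.matrix[~test_mask])
        x_train = std.transform(features.matrix[~test_mask])
        x_test = std.transform(features.matrix[test_mask])
        model = classifiers.fit(spec, x_train, features.labels[~test_mask])
        table = grouped_permutation_importance(
            model,
            FeatureMatrix(x_test, features.feature_meta,
                          features.labels[test_mask], features.groups[test_mask]),
            features.labels[test_mask], n_repeats=n_repeats, seed=seed + fold,
        )
        vals = table.table["importance"].to_numpy()
        if base is None:
            base = table.table.drop(columns="importance")
            acc = vals
        else:
            acc = acc + vals
    assert acc is not None and base is not None
    out = base.copy()
    out["importance"] = acc / len(list(use))
    return ImportanceTable(table=out, method="permutation", aggregation="location_channel")


def cv_permutation_importance(
    spec: ModelSpec,
    features: FeatureMatrix,
    k: int = 6,
    seed: int = 0,
    n_repeats: int = 10,
    n_folds_used: int | None = None,
) -> ImportanceTable:
    """Permutation importance per held-out fold, averaged across folds.

    ``n_folds_used`` computes the (seeded) average over only the first
    few folds — a cost control for wide feature matrices.
    """
    assignment = grouped_folds(features.groups, k, seed)
    fold_idx = np.array([assignment.group_to_fold[g] for g in features.groups])
    use = range(k if n_folds_used is None else min(n_folds_used, k))
    acc: np.ndarray | None = None
    for fold in use:
        test_mask = fold_idx == fold
        _assert_no_leakage(features.groups[~test_mask], features.groups[test_mask])
        std = fit_standardizer(features.matrix[~test_mask])
        x_train = std.transform(features.matrix[~test_mask])
        x_test = std.transform(features.matrix[test_mask])
        model = classifiers.fit(spec, x_train, features.labels[~test_mask])
        table = permutation_importance(
            model, FeatureMatrix(x_test, features.feature_meta,
                                 features.labels[test_mask],
                                 features.groups[test_mask]),
            features.labels[test_mask], n_repeats=n_repeats,
            seed=seed + fold,
        )
        vals = table.table["importance"].to_numpy()
        acc = vals if acc is None else acc + vals
    assert acc is not None
    out = features.feature_meta.reset_index(drop=True).copy()
    out["importance"] = acc / len(list(use))
    return ImportanceTable(table=out, method="permutation")


def group_importance(table: ImportanceTable, by: str = "location_channel") -> pd.DataFrame:
    """Sum importances across subchannel axes and engineered features.

    ``by="location_channel"`` returns a grid with device locations as
    rows and sensor channels as columns; ``"location"`` / ``"channel"``
    return one summed series each.
    """
    df = table.table
    required = {"location", "channel", "importance"}
    if not required.issubset(df.columns) or df["location"].eq("").all():
        raise ValueError("importance table lacks location/channel metadata")
    if by == "location_channel":
        grid = df.pivot_table(
            index="location", columns="channel", values="importance",
            aggfunc="sum", fill_value=0.0,
        )
        rows = [l for l in LOCATIONS if l in grid.index]
        cols = [c for c in CHANNELS if c in grid.columns]
        return grid.loc[rows, cols]
    if by in ("location", "channel"):
        series = df.groupby(by)["importance"].sum()
        order = LOCATIONS if by == "location" else CHANNELS
        return series.reindex([x for x in order if x in series.index]).to_frame()
    raise ValueError(f"unknown grouping {by!r}")


def export_heatmap(grid: pd.DataFrame, path, title: str = "feature importance") -> None:
    """Render a location x channel importance grid as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(grid.columns) + 2,
                                    0.45 * len(grid.index) + 1.5))
    im = ax.imshow(grid.to_numpy(), cmap="Blues", aspect="auto")
    ax.set_xticks(range(len(grid.columns)), grid.columns, rotation=30, ha="right")
    ax.set_yticks(range(len(grid.index)), grid.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="summed importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
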