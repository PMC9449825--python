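"""Uniform interface over the candidate classifier families.

Nine engineered-feature families (scikit-learn / xgboost estimators
with explicitly frozen "default" settings) plus a 1-D CNN trained
directly on raw segments.  Freezing the defaults here pins down the
moving target of library defaults; hyperparameter names are validated
against a per-family schema so configuration typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cnn import Conv1dClassifier
from .featurizer import FeatureMatrix
from .segmenter import SegmentSet
from .sensordata import ValidationError

__all__ = [
    "FAMILIES",
    "ENGINEERED_FAMILIES",
    "ModelSpec",
    "TrainedModel",
    "SchemaError",
    "fit",
    "predict",
]


class SchemaError(Exception):
    """Unknown model family or hyperparameter name."""


# family -> (frozen defaults, allowed hyperparameter names)
_SCHEMAS: dict[str, tuple[dict[str, Any], set[str]]] = {
    "decision_tree": (
        {"criterion": "gini"},
        {"criterion", "max_depth", "min_samples_split", "min_samples_leaf", "max_features"},
    ),
    "random_forest": (
        {"n_estimators": 100},
        {"n_estimators", "max_features", "min_samples_leaf", "min_samples_split", "max_depth"},
    ),
    "xgboost": (
        {"n_estimators": 100, "learning_rate": 0.3, "max_depth": 6},
        {"n_estimators", "learning_rate", "max_depth", "colsample_bytree",
         "gamma", "min_child_weight", "subsample"},
    ),
    "knn": (
        {"n_neighbors": 5, "metric": "euclidean"},
        {"n_neighbors", "weights", "metric"},
    ),
    "sgd_linear_svm": (
        {"loss": "hinge"},
        {"alpha", "penalty", "max_iter"},
    ),
    "lda": ({"solver": "svd"}, {"solver", "shrinkage"}),
    "gaussian_nb": ({}, {"var_smoothing"}),
    "svm": ({"kernel": "rbf", "C": 1.0}, {"C", "kernel", "gamma"}),
    "mlp": (
        {"hidden_layer_sizes": (100,), "activation": "relu", "solver": "adam"},
        {"hidden_layer_sizes", "alpha", "learning_rate_init", "max_iter"},
    ),
    "cnn": (
        {"conv_channels": (128, 256, 128), "kernel_sizes": (8, 5, 3),
         "epochs": 100, "learning_rate": 0.001, "batch_size": 32},
        {"conv_channels", "kernel_sizes", "epochs", "learning_rate", "batch_size"},
    ),
}

FAMILIES: tuple[str, ...] = tuple(_SCHEMAS)
ENGINEERED_FAMILIES: tuple[str, ...] = tuple(f for f in FAMILIES if f != "cnn")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with hyperparameter overrides and a seed."""

    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _SCHEMAS:
            raise SchemaError(
                f"unknown family {self.family!r}; valid families: {sorted(_SCHEMAS)}"
            )
        _, allowed = _SCHEMAS[self.family]
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise SchemaError(
                f"{self.family}: unknown hyperparameters {sorted(unknown)}; "
                f"valid names: {sorted(allowed)}"
            )

    def resolved(self) -> dict[str, Any]:
        defaults, _ = _SCHEMAS[self.family]
        out = dict(defaults)
        out.update(self.hyperparameters)
        return out

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }


def _build_estimator(spec: ModelSpec):
    params = spec.resolved()
    seed = spec.seed
    family = spec.family
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, tree_method="hist", **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "sgd_linear_svm":
        return SGDClassifier(random_state=seed, **params)
    if family == "lda":
        return LinearDiscriminantAnalysis(**params)
    if family == "gaussian_nb":
        return GaussianNB(**params)
    if family == "svm":
        return SVC(random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(random_state=seed, **params)
    if family == "cnn":
        return Conv1dClassifier(seed=seed, **params)
    raise SchemaError(family)


@dataclass
class TrainedModel:
    """A fitted classifier plus the input layout it expects."""

    spec: ModelSpec
    estimator: Any
    classes: np.ndarray
    input_kind: str  # "features" | "segments"
    input_shape: tuple  # (n_features,) or (width, channels)
    label_encoder: LabelEncoder | None = None

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def _as_feature_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.matrix
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValidationError(
            f"engineered-feature families expect a 2-D feature matrix, got ndim={arr.ndim}"
        )
    return arr


def _as_segment_tensor(X) -> np.ndarray:
    if isinstance(X, SegmentSet):
        return X.tensor
    arr = np.asarray(X)
    if arr.ndim != 3:
        raise ValidationError(
            f"the cnn family expects segments of shape (n, width, channels), got ndim={arr.ndim}"
        )
    return arr


def fit(spec: ModelSpec, X, y) -> TrainedModel:
    """Train one model.  Engineered families take a FeatureMatrix (or
    2-D array); the cnn takes a SegmentSet (or 3-D array)."""
    y = np.asarray(y)
    estimator = _build_estimator(spec)
    if spec.family == "cnn":
        tensor = _as_segment_tensor(X)
        estimator.fit(tensor, y)
        return TrainedModel(
            spec=spec, estimator=estimator, classes=np.asarray(estimator.classes_),
            input_kind="segments", input_shape=tensor.shape[1:],
        )
    matrix = _as_feature_array(X)
    encoder = None
    y_fit = y
    if spec.family == "xgboost":
        encoder = LabelEncoder().fit(y)
        y_fit = encoder.transform(y)
    estimator.fit(matrix, y_fit)
    classes = encoder.classes_ if encoder is not None else np.asarray(estimator.classes_)
    return TrainedModel(
        spec=spec, estimator=estimator, classes=classes,
        input_kind="features", input_shape=(matrix.shape[1],),
        label_encoder=encoder,
    )


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained engineered-feature model (joblib + version stamp)."""
    import joblib

    from . import __version__

    joblib.dump({"imurehab_version": __version__, "model": model}, path)


def load_model(path) -> TrainedModel:
    import joblib

    payload = joblib.load(path)
    return payload["model"]


def predict(model: TrainedModel, X) -> np.ndarray:
    """One label per row/segment, drawn from the training label set."""
    if model.input_kind == "segments":
        tensor = _as_segment_tensor(X)
        if tensor.shape[0] == 0:
            return model.classes[:0]
        if tensor.shape[1:] != model.input_shape:
            raise ValidationError(
                f"segment layout {tensor.shape[1:]} != training layout {model.input_shape}"
            )
        return model.estimator.predict(tensor)
    matrix = _as_feature_array(X)
    if matrix.shape[0] == 0:
        return model.classes[:0]
    if matrix.shape[1] != model.input_shape[0]:
        raise ValidationError(
            f"feature count {matrix.shape[1]} != training count {model.input_shape[0]}"
        )
    pred = model.estimator.predict(matrix)
    if model.label_encoder is not None:
        pred = model.label_encoder.inverse_transform(pred.astype(int))
    return np.asarray(pred)
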