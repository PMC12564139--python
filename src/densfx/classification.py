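"""Stage-2 classifiers over radiomic feature vectors, plus the evaluation
metrics shared by both models (accuracy and balanced accuracy).

The six algorithms are the established scikit-learn estimators; the bespoke
content of this module is the metric layer, class weighting, feature-schema
bookkeeping and the deterministic fit/evaluate harness. The positive class
is 1 (= fracture).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateInputError, ParameterError, SchemaError, ValidationError

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "FittedClassifier",
    "EvalResult",
    "fit_classifier",
    "predict",
    "evaluate",
    "balanced_accuracy",
    "confusion_counts",
]

ALGORITHMS = (
    "decision_tree",
    "extra_trees",
    "gradient_boosting",
    "knn",
    "gaussian_nb",
    "random_forest",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice and harness options.

    ``standardize_features=None`` auto-enables z-scoring (with training-set
    statistics) for the distance-based KNN and leaves scale-invariant tree
    methods on raw features. Defaults: KNN k=5 Euclidean; ensembles with 100
    estimators, seeded.
    """

    algorithm: str = "knn"
    hyperparameters: dict = field(default_factory=dict)
    class_weighting: bool = False
    standardize_features: bool | None = None
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.algorithm == "knn" and self.hyperparameters.get("n_neighbors", 1) < 1:
            raise ParameterError("knn needs n_neighbors >= 1")

    @property
    def standardize(self) -> bool:
        if self.standardize_features is None:
            return self.algorithm == "knn"
        return self.standardize_features


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    cw = "balanced" if spec.class_weighting else None
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, class_weight=cw, **hp)
    if spec.algorithm == "extra_trees":
        hp.setdefault("n_estimators", 100)
        return ExtraTreesClassifier(random_state=spec.seed, class_weight=cw, **hp)
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, class_weight=cw, **hp)
    if spec.algorithm == "gradient_boosting":
        hp.setdefault("n_estimators", 100)
        return GradientBoostingClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if spec.algorithm == "gaussian_nb":
        return GaussianNB(**hp)
    raise ParameterError(spec.algorithm)  # pragma: no cover


@dataclass
class FittedClassifier:
    pipeline: Pipeline
    schema: tuple
    spec: ClassifierSpec


def _as_matrix(features) -> tuple:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=np.float64), tuple(features.columns)
    x = np.asarray(features, dtype=np.float64)
    return x, tuple(f"f{i}" for i in range(x.shape[1]))


def fit_classifier(features, labels, spec: ClassifierSpec) -> FittedClassifier:
    """Fit one classifier; deterministic given ``spec.seed``.

    Standardization statistics (when enabled) come from the training data
    only and travel with the fitted pipeline.
    """
    x, schema = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(x)):
        raise ValidationError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", _build_estimator(spec)))
    pipe = Pipeline(steps)
    fit_params = {}
    if spec.class_weighting and spec.algorithm in ("gradient_boosting", "gaussian_nb"):
        # these estimators take no class_weight; use per-sample weights instead
        counts = np.bincount(y, minlength=2)
        w = y.size / (2.0 * counts[y])
        fit_params["clf__sample_weight"] = w
    pipe.fit(x, y, **fit_params)
    return FittedClassifier(pipeline=pipe, schema=schema, spec=spec)


def _check_schema(model: FittedClassifier, features) -> np.ndarray:
    x, schema = _as_matrix(features)
    if schema != model.schema:
        raise SchemaError(
            f"feature schema mismatch: model fitted on {model.schema[:4]}... "
            f"({len(model.schema)} cols), got {schema[:4]}... ({len(schema)} cols)"
        )
    return x


def predict(model: FittedClassifier, features) -> np.ndarray:
    x = _check_schema(model, features)
    return model.pipeline.predict(x).astype(int)


def confusion_counts(y_true, y_pred) -> dict:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    return {
        "tp": int(((yt == 1) & (yp == 1)).sum()),
        "fp": int(((yt == 0) & (yp == 1)).sum()),
        "tn": int(((yt == 0) & (yp == 0)).sum()),
        "fn": int(((yt == 1) & (yp == 0)).sum()),
    }


def balanced_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """Mean of sensitivity and specificity; undefined if a class is absent."""
    if tp + fn == 0 or tn + fp == 0:
        raise DegenerateInputError(
            "balanced accuracy undefined: one class absent from the reference labels"
        )
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and summary metrics for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    balanced_accuracy: float
    predictions: tuple

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate(model: FittedClassifier, features, labels) -> EvalResult:
    """Pure evaluation: repeated calls on the same inputs are identical."""
    y = np.asarray(labels).astype(int)
    yp = predict(model, features)
    cc = confusion_counts(y, yp)
    acc = (cc["tp"] + cc["tn"]) / y.size
    bacc = balanced_accuracy(**cc)
    return EvalResult(
        **cc, accuracy=float(acc), balanced_accuracy=float(bacc), predictions=tuple(int(v) for v in yp)
    )
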