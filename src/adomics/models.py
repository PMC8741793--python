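"""Uniform interface over the classifier families, with threshold tuning.

Five families are supported — logistic regression, SVM with linear or rbf
kernel, random forest, and gradient-boosted trees — each exposing class-1
probabilities so the decision threshold p_t can be tuned separately from
the fit (a sample is called a case iff its predicted probability strictly
exceeds p_t; the default is 0.5). SVM probabilities come from the
estimator's internal calibration, seeded for determinism.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "fit",
    "predict_proba",
    "classify",
    "tune_threshold",
    "save_model",
    "load_model",
]

FAMILIES = (
    "logistic_regression",
    "svm_linear",
    "svm_rbf",
    "random_forest",
    "gradient_boosted_trees",
)

_ARTIFACT_VERSION = 1


@dataclass
class ClassifierSpec:
    """Model family + hyperparameter overrides + seed."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; expected one of {FAMILIES}"
            )

    def build(self):
        hp = dict(self.hyperparameters)
        if self.family == "logistic_regression":
            hp.setdefault("max_iter", 2000)
            return LogisticRegression(**hp)
        if self.family == "svm_linear":
            hp.setdefault("probability", True)
            return SVC(kernel="linear", random_state=self.seed, **hp)
        if self.family == "svm_rbf":
            hp.setdefault("probability", True)
            return SVC(kernel="rbf", random_state=self.seed, **hp)
        if self.family == "random_forest":
            hp.setdefault("n_estimators", 100)
            return RandomForestClassifier(random_state=self.seed, **hp)
        hp.setdefault("n_estimators", 100)
        hp.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=self.seed, verbosity=0, **hp)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }


@dataclass
class TrainedClassifier:
    """A fitted estimator bound to the exact ordered feature list it saw."""

    spec: ClassifierSpec
    estimator: Any
    feature_ids: list[str]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


def fit(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
) -> TrainedClassifier:
    """Fit one classifier; deterministic under the spec's seed."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    est = spec.build()
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates SVC(probability=True); the calibrated
        # probability output is still the behaviour we want here
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        est.fit(X_train, y_train)
    ids = (
        [str(f) for f in feature_ids]
        if feature_ids is not None
        else [f"f{i}" for i in range(X_train.shape[1])]
    )
    if len(ids) != X_train.shape[1]:
        raise ValueError("feature_ids length does not match X_train width")
    return TrainedClassifier(spec, est, ids)


def predict_proba(
    model: TrainedClassifier,
    X: np.ndarray,
    feature_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Class-1 probabilities; refuses a column order differing from training."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.feature_ids):
        raise ValueError(
            f"expected {len(model.feature_ids)} feature columns, got {X.shape[1]}"
        )
    if feature_ids is not None:
        for given, expected in zip(feature_ids, model.feature_ids):
            if str(given) != expected:
                raise ValueError(
                    f"feature column mismatch: got {given!r} where the model "
                    f"was trained on {expected!r}"
                )
    proba = model.estimator.predict_proba(X)
    class_index = list(model.estimator.classes_).index(1)
    return proba[:, class_index]


def classify(probabilities: np.ndarray, p_t: float = 0.5) -> np.ndarray:
    """Label 1 iff probability strictly exceeds p_t."""
    if not 0 < p_t < 1:
        raise ValueError(f"p_t must be in (0, 1), got {p_t}")
    return (np.asarray(probabilities, dtype=float) > p_t).astype(int)


def tune_threshold(
    model_spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: Sequence[float],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Choose p_t by stratified-CV mean F1 over a threshold grid.

    One fit per fold serves the whole grid. Ties go to the value closest to
    0.5 (then the smaller), keeping the choice conservative.
    """
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(not 0 < t < 1 for t in grid):
        raise ValueError("thresholds must lie in (0, 1)")
    from adomics.metrics import confusion, metrics  # local import: avoid cycle

    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((n_folds, len(grid)))
    for fi, (tr, va) in enumerate(skf.split(X_train, y_train)):
        model = fit(model_spec, X_train[tr], y_train[tr])
        proba = predict_proba(model, X_train[va])
        for ti, t in enumerate(grid):
            pred = classify(proba, t)
            scores[fi, ti] = metrics(confusion(pred, y_train[va])).f1
    trace = scores.mean(axis=0)
    best_idx = min(
        (i for i in range(len(grid)) if trace[i] == trace.max()),
        key=lambda i: (abs(grid[i] - 0.5), grid[i]),
    )
    return grid[best_idx], [float(v) for v in trace]


def save_model(model: TrainedClassifier, path: str | Path) -> Path:
    """Persist a trained classifier with its feature-ID manifest."""
    path = Path(path)
    payload = {
        "version": _ARTIFACT_VERSION,
        "spec": model.spec.to_dict(),
        "feature_ids": list(model.feature_ids),
        "threshold": model.threshold,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)
    return path


def load_model(path: str | Path) -> TrainedClassifier:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != _ARTIFACT_VERSION:
        raise ValueError(
            f"unsupported model artifact version {payload.get('version')!r}"
        )
    spec = ClassifierSpec(**payload["spec"])
    return TrainedClassifier(
        spec, payload["estimator"], payload["feature_ids"], payload["threshold"]
    )
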