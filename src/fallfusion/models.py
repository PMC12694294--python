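"""Classifier families, the majority-voter ensemble, and task labeling.

Four traditional families are benchmarked — random forest (RF), RBF
support-vector machine (SVM), gradient-boosted trees (XGB) and logistic
regression (LR) — plus a majority voter (MV) over all four. Training is
made deterministic given (data, seed): rows are put into a canonical
order before fitting so that permuting the caller's row order cannot
change bootstrap draws or optimizer summation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .config import _default_hyperparams
from .errors import DataError, UsageError

FAMILIES = ("RF", "SVM", "XGB", "LR")
BINARY_LABELS = ("ADL", "FALL")

_ADL_ACTIVITIES = {"jumping", "running", "sitting", "walking"}


def make_task_labels(labels: pd.Series | np.ndarray, task: str) -> np.ndarray:
    """Map activity labels to the task vocabulary.

    ``binary`` collapses {jumping, running, sitting, walking} to ``ADL``
    and ``falling`` to ``FALL``; ``multiclass`` passes the five
    activities through unchanged.
    """
    labels = np.asarray(labels, dtype=object)
    known = _ADL_ACTIVITIES | {"falling"}
    bad = set(labels) - known
    if bad:
        raise DataError(f"unknown activity label(s): {sorted(bad)}")
    if task == "multiclass":
        return labels.astype(str)
    if task == "binary":
        return np.where(np.isin(labels, list(_ADL_ACTIVITIES)), "ADL", "FALL").astype(str)
    raise UsageError(f"unknown task {task!r} (expected binary|multiclass)")


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameters and seed."""

    family: str
    params: dict[str, Any] = field(default_factory=dict)
    task: str = "multiclass"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UsageError(f"unknown family {self.family!r} (expected one of {FAMILIES})")
        defaults = dict(_default_hyperparams()[self.family])
        defaults.update(self.params)
        self.params = defaults


@dataclass
class EnsembleSpec:
    """Majority voter over member families (default: all four)."""

    members: tuple[str, ...] = FAMILIES
    task: str = "multiclass"
    seed: int = 0
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise UsageError("an ensemble needs at least 2 members")

    def member_specs(self) -> list[ModelSpec]:
        return [
            ModelSpec(m, dict(self.params.get(m, {})), task=self.task, seed=self.seed)
            for m in self.members
        ]


@dataclass
class Prediction:
    """Predicted labels plus a per-class probability matrix (rows sum to 1)."""

    labels: np.ndarray
    proba: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        if self.proba.shape != (len(self.labels), len(self.classes)):
            raise UsageError("probability matrix shape does not match labels/classes")


def _build_estimator(spec: ModelSpec):
    p = spec.params
    if spec.family == "RF":
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.family == "SVM":
        return SVC(probability=True, random_state=spec.seed, **p)
    if spec.family == "XGB":
        return XGBClassifier(
            random_state=spec.seed,
            eval_metric="mlogloss",
            n_jobs=1,
            verbosity=0,
            **p,
        )
    if spec.family == "LR":
        return LogisticRegression(**p)
    raise UsageError(spec.family)


class FittedModel:
    """Handle around a fitted estimator with string-label predict/proba."""

    def __init__(self, spec: ModelSpec, estimator, classes: list[str]):
        self.spec = spec
        self.estimator = estimator
        self.classes = classes

    def predict(self, X: np.ndarray) -> Prediction:
        X = np.asarray(X, float)
        proba = self.estimator.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        labels = np.array([self.classes[i] for i in idx], dtype=object)
        return Prediction(labels=labels, proba=proba, classes=list(self.classes))


def train_model(spec: ModelSpec, X: np.ndarray | pd.DataFrame, y: np.ndarray) -> FittedModel:
    """Fit one classifier; deterministic given (data, seed).

    Rows are sorted into a canonical (lexicographic) order before
    fitting so that the result is invariant to the caller's row
    ordering. Class labels are encoded to integers internally (XGB
    requires it) and decoded on predict.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or len(X) != len(y):
        raise DataError("X must be 2-D with one row per label")
    classes = sorted(set(y.astype(str)))
    if len(classes) < 2:
        raise DataError("training labels contain a single class")
    code = {c: i for i, c in enumerate(classes)}
    y_enc = np.array([code[str(v)] for v in y])
    order = np.lexsort(np.vstack([y_enc, X.T[::-1]]))
    est = _build_estimator(spec)
    est.fit(X[order], y_enc[order])
    # sklearn orders predict_proba columns by sorted encoded class
    return FittedModel(spec, est, classes)


def majority_vote(predictions: list[Prediction]) -> Prediction:
    """Modal label across member predictions.

    Ties are broken toward the tied class with the highest mean
    predicted probability across members; the ensemble probability is
    the mean of the member probability matrices.
    """
    if len(predictions) < 2:
        raise UsageError("majority vote needs at least 2 member predictions")
    classes = predictions[0].classes
    n = len(predictions[0].labels)
    for p in predictions[1:]:
        if p.classes != classes or len(p.labels) != n:
            raise UsageError("member predictions disagree on recordings or class set")
    mean_proba = np.mean([p.proba for p in predictions], axis=0)
    votes = np.zeros((n, len(classes)), dtype=int)
    cidx = {c: i for i, c in enumerate(classes)}
    for p in predictions:
        for r, lab in enumerate(p.labels):
            votes[r, cidx[str(lab)]] += 1
    labels = np.empty(n, dtype=object)
    for r in range(n):
        top = votes[r].max()
        tied = np.flatnonzero(votes[r] == top)
        if len(tied) == 1:
            labels[r] = classes[tied[0]]
        else:
            best = tied[np.argmax(mean_proba[r, tied])]
            labels[r] = classes[best]
    return Prediction(labels=labels, proba=mean_proba, classes=list(classes))
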