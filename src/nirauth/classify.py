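"""Multi-class baselines (DT, SVM, ANN, NB) with pooled-CV and hold-out
confusion reporting.  Estimators are scikit-learn; the evaluation
arithmetic is native."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

KINDS = ("DT", "SVM", "ANN", "NB")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


def make_estimator(spec: ClassifierSpec):
    if spec.kind == "DT":
        return DecisionTreeClassifier(random_state=spec.seed, **spec.params)
    if spec.kind == "SVM":
        params = {"kernel": "linear", "C": 1.0, **spec.params}
        return SVC(random_state=spec.seed, **params)
    if spec.kind == "ANN":
        params = {"hidden_layer_sizes": (25,), "early_stopping": True,
                  "max_iter": 1000, **spec.params}
        return MLPClassifier(random_state=spec.seed, **params)
    return GaussianNB(**spec.params)


@dataclass(frozen=True)
class ConfusionReport:
    classes: np.ndarray
    matrix: np.ndarray  # rows = true class, columns = predicted

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.classes.size, self.classes.size):
            raise ValueError("confusion matrix shape mismatch")
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.matrix.sum())

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return np.diag(self.matrix) / self.matrix.sum(axis=1)


def _confusion(classes: np.ndarray, y_true, y_pred) -> ConfusionReport:
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return ConfusionReport(classes, mat)


def crossval(spec: ClassifierSpec, X, labels, folds: int = 10,
             seed: int = 0) -> ConfusionReport:
    """Stratified K-fold CV; out-of-fold predictions pooled into one matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        small = classes[int(np.argmin(counts))]
        raise ValueError(f"class {small!r} has only {counts.min()} members; "
                         f"use at most {counts.min()} folds")
    y_pred = np.empty_like(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        est = make_estimator(spec)
        est.fit(X[train], y[train])
        y_pred[test] = est.predict(X[test])
    return _confusion(classes, y, y_pred)


def holdout_eval(spec: ClassifierSpec, X_train, y_train, X_test, y_test,
                 train_idx=None, test_idx=None) -> ConfusionReport:
    """Fit on the training set, evaluate once on the disjoint test set."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if train_idx is not None and test_idx is not None:
        if np.intersect1d(train_idx, test_idx).size:
            raise ValueError("train and test index sets overlap")
    else:
        train_rows = {row.tobytes() for row in X_train}
        if any(row.tobytes() in train_rows for row in X_test):
            raise ValueError("test set contains rows identical to training "
                             "rows: sets must be disjoint")
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    est = make_estimator(spec)
    est.fit(X_train, y_train)
    classes = np.unique(np.concatenate([y_train, y_test]))
    return _confusion(classes, y_test, est.predict(X_test))
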