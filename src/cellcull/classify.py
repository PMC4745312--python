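"""Suitability classifiers: kernel SVM plus kNN and random-forest baselines.

The working classifier is a Gaussian (RBF) kernel SVM whose penalty C and
kernel scale sigma are tuned by stratified k-fold cross-validation over log
grids. Features are standardized inside the model pipeline, so the scaler is
fit on training folds only and test leakage is structurally impossible.
Decision scores are oriented so that larger means more likely suitable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

POSITIVE_LABEL = "suitable"
NEGATIVE_LABEL = "unsuitable"

#: default log grids for SVM tuning
DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))
DEFAULT_DEGREES = (2, 3)


def kernel(u, v, kind: str = "rbf", *, sigma: float = 1.0,
           degree: int = 3, offset: float = 1.0) -> float:
    """Kernel value between two feature vectors.

    linear: <u, v>; polynomial: (<u, v> + a)^d; rbf: exp(-||u-v||^2 / 2 sigma^2).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if kind == "linear":
        return float(u @ v)
    if kind == "polynomial":
        return float((u @ v + offset) ** degree)
    if kind == "rbf":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return float(np.exp(-np.sum((u - v) ** 2) / (2.0 * sigma ** 2)))
    raise ValueError("kind must be 'linear', 'polynomial' or 'rbf'")


@dataclass
class TrainedClassifier:
    method: str  # "svm" | "knn" | "rf"
    kernel: str | None
    model: Pipeline
    feature_names: list[str]
    params: dict = field(default_factory=dict)
    seed: int = 0
    cv_results: dict | None = None

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        cols = [c for c in table.columns if c != "label"]
        missing = [c for c in self.feature_names if c not in cols]
        extra = [c for c in cols if c not in self.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature names do not match training: missing={missing}, "
                f"extra={extra}")
        return table[self.feature_names].to_numpy(dtype=np.float64)


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(labels) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    return (labels == POSITIVE_LABEL).astype(int)


def train(table: pd.DataFrame, method: str = "svm", kernel: str = "rbf",
          grid: dict | None = None, folds: int = 10, seed: int = 0,
          k_neighbors: int = 3, n_trees: int = 500) -> TrainedClassifier:
    """Fit a classifier on a labeled feature table.

    For SVMs, hyperparameters are selected by ``folds``-fold stratified CV
    accuracy over a log grid (``grid`` maps ``C``/``sigma``/``degree`` to
    candidate lists). kNN uses k=3 and RF 500 trees with sqrt(p) features per
    split unless overridden. Fold assignment is deterministic in ``seed``.
    """
    if "label" not in table.columns:
        raise ValueError("training table needs a 'label' column")
    feature_names = [c for c in table.columns if c != "label"]
    X = table[feature_names].to_numpy(dtype=np.float64)
    y = _encode(table["label"])
    counts = np.bincount(y, minlength=2)
    if method == "svm" and counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; needs >= {folds} folds")

    if method == "svm":
        grid = grid or {}
        Cs = list(grid.get("C", DEFAULT_C_GRID))
        sigmas = list(grid.get("sigma", DEFAULT_GAMMA_GRID))
        if kernel == "rbf":
            param_grid = {"svc__C": Cs,
                          "svc__gamma": [1.0 / (2.0 * s ** 2) for s in sigmas]}
            svc = SVC(kernel="rbf")
        elif kernel == "linear":
            param_grid = {"svc__C": Cs}
            svc = SVC(kernel="linear")
        elif kernel == "polynomial":
            param_grid = {"svc__C": Cs,
                          "svc__degree": list(grid.get("degree", DEFAULT_DEGREES))}
            svc = SVC(kernel="poly", gamma=1.0, coef0=grid.get("offset", 1.0))
        else:
            raise ValueError("kernel must be 'linear', 'polynomial' or 'rbf'")
        pipe = Pipeline([("scale", StandardScaler()), ("svc", svc)])
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, param_grid, cv=cv, scoring="accuracy",
                              refit=True)
        search.fit(X, y)
        model = search.best_estimator_
        params = dict(search.best_params_)
        cv_results = {
            "mean_test_score": search.cv_results_["mean_test_score"].tolist(),
            "params": [dict(p) for p in search.cv_results_["params"]],
        }
    elif method == "knn":
        model = Pipeline([("scale", StandardScaler()),
                          ("knn", KNeighborsClassifier(n_neighbors=k_neighbors))])
        model.fit(X, y)
        params = {"k": k_neighbors}
        cv_results = None
    elif method == "rf":
        model = Pipeline([("rf", RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed))])
        model.fit(X, y)
        params = {"n_trees": n_trees, "max_features": "sqrt"}
        cv_results = None
    else:
        raise ValueError("method must be 'svm', 'knn' or 'rf'")

    return TrainedClassifier(method=method,
                             kernel=kernel if method == "svm" else None,
                             model=model, feature_names=feature_names,
                             params=params, seed=seed, cv_results=cv_results)


def decision_scores(clf: TrainedClassifier, table: pd.DataFrame) -> np.ndarray:
    """Continuous scores, higher = more confidently suitable."""
    X = clf._matrix(table)
    if clf.method == "svm":
        return clf.model.decision_function(X)
    proba = clf.model.predict_proba(X)
    classes = list(clf.model.classes_)
    return proba[:, classes.index(1)]


def predict(clf: TrainedClassifier, table: pd.DataFrame,
            threshold: float | None = None) -> np.ndarray:
    """Predicted labels at the default decision threshold (or a custom one)."""
    if threshold is None:
        X = clf._matrix(table)
        y = clf.model.predict(X)
    else:
        y = (decision_scores(clf, table) > threshold).astype(int)
    return np.where(y == 1, POSITIVE_LABEL, NEGATIVE_LABEL)
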