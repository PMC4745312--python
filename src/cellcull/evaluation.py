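"""Performance metrics: error rate, sensitivity, ROC/AUC, bootstrap CIs,
feature-count sweeps with a leave-one-out overtraining audit, and effect size.

The positive class is "suitable" throughout (sensitivity = suitable-cell
recall). Confidence intervals are stratified percentile bootstrap intervals
(5th/95th percentiles by default). The overtraining audit follows the
train/test error gap as the feature count grows and summarizes its trend with
a one-sided Kendall-tau test: a significantly increasing gap flags
overtraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classify import (POSITIVE_LABEL, TrainedClassifier, decision_scores,
                       predict, train)

DEFAULT_BOOTSTRAP = 1000


def _binarize(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        return (labels == POSITIVE_LABEL).astype(int)
    return labels.astype(int)


def error_rate(predicted, truth) -> float:
    """Misclassified objects over total objects."""
    p = _binarize(predicted)
    t = _binarize(truth)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    return float(np.mean(p != t))


def accuracy(predicted, truth) -> float:
    return 1.0 - error_rate(predicted, truth)


def sensitivity(predicted, truth) -> float:
    """True positives / actual positives (positive class = suitable)."""
    p = _binarize(predicted)
    t = _binarize(truth)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    npos = int(t.sum())
    if npos == 0:
        raise ValueError("sensitivity undefined: no positive objects present")
    return float(np.sum(p[t == 1] == 1) / npos)


def specificity(predicted, truth) -> float:
    p = _binarize(predicted)
    t = _binarize(truth)
    nneg = int((t == 0).sum())
    if nneg == 0:
        raise ValueError("specificity undefined: no negative objects present")
    return float(np.sum(p[t == 0] == 0) / nneg)


def roc_points(scores, truth) -> np.ndarray:
    """Threshold-sweep ROC as an (m, 2) array of (FPR, TPR) points.

    Anchored at (0, 0) and (1, 1), monotone nondecreasing in both
    coordinates; ties in the scores are handled by the sweep (equivalent to
    counting tied positive/negative pairs as half-concordant in the AUC).
    """
    t = _binarize(truth)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(t, np.asarray(scores, dtype=np.float64),
                                drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(scores, truth) -> float:
    """Trapezoid area under the ROC curve (the c-statistic)."""
    pts = roc_points(scores, truth)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def effect_size(group_a, group_b) -> float:
    """(mean_a - mean_b) / sqrt(var_a + var_b)."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        raise ValueError("effect size undefined: both variances zero")
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(metric_fn, scores, truth, B: int = DEFAULT_BOOTSTRAP,
                 seed: int = 0, percentiles=(5.0, 95.0)):
    """Stratified percentile bootstrap interval of ``metric_fn(scores, truth)``.

    Resampling is done within each class so every resample keeps both classes.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scores = np.asarray(scores)
    t = _binarize(truth)
    rng = np.random.default_rng(seed)
    idx_pos = np.nonzero(t == 1)[0]
    idx_neg = np.nonzero(t == 0)[0]
    values = np.empty(B)
    for b in range(B):
        take = np.concatenate([
            rng.choice(idx_pos, size=idx_pos.size, replace=True),
            rng.choice(idx_neg, size=idx_neg.size, replace=True),
        ])
        values[b] = metric_fn(scores[take], t[take])
    lo, hi = np.percentile(values, percentiles)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    error_rate: float
    sensitivity: float
    specificity: float
    auc: float
    roc: np.ndarray
    ci: dict = field(default_factory=dict)  # metric -> (low, high)
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return {
            "error_rate": self.error_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "roc": self.roc.tolist(),
            "ci": {k: [float(a), float(c)] for k, (a, c) in self.ci.items()},
            "n_bootstrap": self.n_bootstrap,
        }


def evaluate(clf: TrainedClassifier, table: pd.DataFrame,
             B: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> EvalReport:
    """Score a classifier on a labeled test table with bootstrap CIs."""
    truth = _binarize(table["label"])
    scores = decision_scores(clf, table)
    predicted = _binarize(predict(clf, table))

    report = EvalReport(
        error_rate=error_rate(predicted, truth),
        sensitivity=sensitivity(predicted, truth),
        specificity=specificity(predicted, truth),
        auc=auc(scores, truth),
        roc=roc_points(scores, truth),
        n_bootstrap=B,
    )
    if B:
        # resample (prediction, score, truth) triples jointly
        stacked = np.column_stack([scores, predicted]).astype(np.float64)
        report.ci["auc"] = bootstrap_ci(
            lambda s, t: auc(s[:, 0], t), stacked, truth, B=B, seed=seed)
        report.ci["error_rate"] = bootstrap_ci(
            lambda s, t: error_rate(s[:, 1].astype(int), t), stacked, truth,
            B=B, seed=seed)
        report.ci["sensitivity"] = bootstrap_ci(
            lambda s, t: sensitivity(s[:, 1].astype(int), t), stacked, truth,
            B=B, seed=seed)
    return report


# ---------------------------------------------------------------------------
# feature-count sweep and overtraining audit
# ---------------------------------------------------------------------------

def loocv_error(table: pd.DataFrame, method: str = "svm", kernel: str = "rbf",
                params: dict | None = None, seed: int = 0) -> float:
    """Leave-one-out error with fixed hyperparameters (no per-fold retuning)."""
    from sklearn.model_selection import LeaveOneOut
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    from .classify import _encode

    feature_names = [c for c in table.columns if c != "label"]
    X = table[feature_names].to_numpy(dtype=np.float64)
    y = _encode(table["label"])
    params = params or {}
    wrong = 0
    for train_idx, test_idx in LeaveOneOut().split(X):
        model = Pipeline([("scale", StandardScaler()),
                          ("svc", SVC(kernel="rbf" if kernel == "rbf" else kernel,
                                      C=params.get("svc__C", 1.0),
                                      gamma=params.get("svc__gamma", "scale")))])
        model.fit(X[train_idx], y[train_idx])
        wrong += int(model.predict(X[test_idx])[0] != y[test_idx][0])
    return wrong / len(y)


def feature_count_sweep(train_table: pd.DataFrame, test_table: pd.DataFrame,
                        ordered_features, max_features: int,
                        seed: int = 0, folds: int = 5, grid: dict | None = None,
                        B: int = 200, loocv: bool = True) -> pd.DataFrame:
    """Train with the top-k features for k = 1..max_features.

    Returns a frame with train/test/LOOCV errors, sensitivity and AUC (with
    bootstrap CIs) per feature count, plus the train-test gap used by the
    overtraining audit.
    """
    ordered_features = list(ordered_features)
    if len(ordered_features) < max_features:
        raise ValueError("selection trace shorter than max_features")
    rows = []
    for k in range(1, max_features + 1):
        feats = ordered_features[:k]
        sub_train = train_table[feats + ["label"]]
        sub_test = test_table[feats + ["label"]]
        clf = train(sub_train, method="svm", kernel="rbf", grid=grid,
                    folds=folds, seed=seed)
        train_err = error_rate(predict(clf, sub_train), sub_train["label"])
        test_err = error_rate(predict(clf, sub_test), sub_test["label"])
        sens = sensitivity(predict(clf, sub_test), sub_test["label"])
        scores = decision_scores(clf, sub_test)
        truth = _binarize(sub_test["label"])
        a = auc(scores, truth)
        lo, hi = bootstrap_ci(lambda s, t: auc(s, t), scores, truth, B=B,
                              seed=seed) if B else (np.nan, np.nan)
        loo = loocv_error(sub_train, params=clf.params, seed=seed) if loocv \
            else np.nan
        rows.append({"n_features": k, "train_error": train_err,
                     "test_error": test_err, "loocv_error": loo,
                     "sensitivity": sens, "auc": a,
                     "auc_ci_low": lo, "auc_ci_high": hi,
                     "gap": test_err - train_err})
    return pd.DataFrame(rows)


def overtraining_trend(sweep: pd.DataFrame):
    """One-sided Kendall-tau test for a systematically increasing gap.

    Returns ``(tau, p_one_sided)``; small p (< 0.05) flags overtraining.
    """
    gaps = sweep["gap"].to_numpy()
    ks = sweep["n_features"].to_numpy()
    if np.allclose(gaps, gaps[0]):
        return 0.0, 1.0
    tau, p_two = stats.kendalltau(ks, gaps)
    if np.isnan(tau):
        return 0.0, 1.0
    p_one = p_two / 2.0 if tau > 0 else 1.0 - p_two / 2.0
    return float(tau), float(p_one)
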