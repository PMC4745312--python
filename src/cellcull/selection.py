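"""Nonparametric separability criterion and floating stepwise feature search.

The criterion is a weighted, nonparametric variant of Fisher's class
separability. For two classes with samples x_k^i, every sample is compared
with an inverse-distance weighted mean of the *other* class (between-class
scatter S_b) and of its *own* class (within-class scatter S_w):

    w_kl      ~ d(x_k^i, x_l^j)^-1          (weights of the weighted mean)
    M_j(x)    = sum_l w_l x_l^j             (weighted mean of x in class j)
    lambda_k  ~ d(x_k^i, M_j(x_k^i))^-1     (per-sample scatter weight,
                                             normalized over class i)
    S_b = sum_i P_i sum_{j != i} sum_k (lambda_k / n_i)
              (x_k^i - M_j(x_k^i)) (x_k^i - M_j(x_k^i))^T
    S_w = analogous with j = i
    F   = trace(S_w^-1 S_b)

Conventions (degenerate cases of inverse-distance weighting):

* a sample is excluded from its *own* within-class weighted mean -- including
  it would make M_i(x) = x and S_w identically zero;
* if a sample coincides with one or more reference points, the weight mass is
  shared equally among the coincident points;
* if some d(x_k, M) = 0, those samples share the class's full lambda mass.

Distances are computed, by default, after whitening by the total covariance
of the candidate subset (Mahalanobis metric), which makes F exactly invariant
under any invertible affine transformation of the feature space. Plain
z-scoring and raw Euclidean distances are selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: relative ridge applied to S_w when it is poorly conditioned
RIDGE = 1e-8


@dataclass
class ScatterPair:
    """Between- and within-class scatter matrices with class metadata."""

    Sb: np.ndarray
    Sw: np.ndarray
    priors: np.ndarray
    counts: np.ndarray


@dataclass
class SelectionTrace:
    """Ordered selected features with the criterion value at every step."""

    selected: list[str] = field(default_factory=list)
    criterion_values: list[float] = field(default_factory=list)
    steps: list[tuple[str, str, float]] = field(default_factory=list)  # (action, name, F)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "criterion_values": [float(v) for v in self.criterion_values],
            "steps": [[a, n, float(f)] for a, n, f in self.steps],
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def inverse_distance_weights(x, class_samples) -> np.ndarray:
    """Normalized 1/d weights of ``x`` against each sample of a class.

    Coincident points (zero distance) share the full mass equally.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    S = np.atleast_2d(np.asarray(class_samples, dtype=np.float64))
    if S.shape[0] == 0:
        raise ValueError("class has no samples")
    d = np.linalg.norm(S - x[None, :], axis=1)
    zero = d == 0
    if zero.any():
        w = zero.astype(np.float64)
        return w / w.sum()
    inv = 1.0 / d
    return inv / inv.sum()


def weighted_mean(x, class_samples) -> np.ndarray:
    """Inverse-distance weighted mean of a class, seen from sample ``x``."""
    S = np.atleast_2d(np.asarray(class_samples, dtype=np.float64))
    w = inverse_distance_weights(x, S)
    return w @ S


def scatter_weights(class_i_samples, reference_class_samples,
                    within: bool = False) -> np.ndarray:
    """Per-sample scatter weights lambda_k of class i against a reference
    class, normalized to sum 1 over class i.

    With ``within=True`` the reference class is class i itself and each
    sample is excluded from its own weighted mean.
    """
    Xi = np.atleast_2d(np.asarray(class_i_samples, dtype=np.float64))
    Xj = np.atleast_2d(np.asarray(reference_class_samples, dtype=np.float64))
    M = _weighted_means(Xi, Xj, exclude_self=within)
    d = np.linalg.norm(Xi - M, axis=1)
    zero = d == 0
    if zero.any():
        logger.debug("zero distance to weighted mean for %d samples", zero.sum())
        lam = zero.astype(np.float64)
        return lam / lam.sum()
    inv = 1.0 / d
    return inv / inv.sum()


def _weighted_means(Xi: np.ndarray, Xj: np.ndarray,
                    exclude_self: bool = False) -> np.ndarray:
    """Weighted mean of class j seen from every sample of class i (rows)."""
    D = cdist(Xi, Xj)
    if exclude_self:
        if Xi.shape[0] != Xj.shape[0]:
            raise ValueError("exclude_self requires Xi is Xj")
        np.fill_diagonal(D, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(D > 0, 1.0 / D, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    zero = (D == 0)
    has_zero = zero.any(axis=1)
    W = np.zeros_like(D)
    norm = inv.sum(axis=1)
    ok = ~has_zero & (norm > 0)
    W[ok] = inv[ok] / norm[ok, None]
    if has_zero.any():
        Z = zero[has_zero].astype(np.float64)
        W[has_zero] = Z / Z.sum(axis=1, keepdims=True)
    return W @ Xj


def _scatter_from_arrays(X0: np.ndarray, X1: np.ndarray) -> ScatterPair:
    """S_b and S_w for two classes given as raw coordinate arrays."""
    classes = [np.atleast_2d(np.asarray(X, dtype=np.float64)) for X in (X0, X1)]
    n = np.array([X.shape[0] for X in classes], dtype=np.float64)
    if (n < 2).any():
        raise ValueError("each class needs at least 2 samples")
    P = n / n.sum()
    d = classes[0].shape[1]
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for i in (0, 1):
        Xi = classes[i]
        for j in (0, 1):
            Xj = classes[j]
            within = i == j
            M = _weighted_means(Xi, Xj, exclude_self=within)
            lam = _lambda_from_means(Xi, M)
            diffs = Xi - M
            S = (diffs * lam[:, None]).T @ diffs / n[i]
            if within:
                Sw += P[i] * S
            else:
                Sb += P[i] * S
    return ScatterPair(Sb=Sb, Sw=Sw, priors=P, counts=n.astype(int))


def _lambda_from_means(Xi, M):
    dist = np.linalg.norm(Xi - M, axis=1)
    zero = dist == 0
    if zero.any():
        lam = zero.astype(np.float64)
        return lam / lam.sum()
    inv = 1.0 / dist
    return inv / inv.sum()


# ---------------------------------------------------------------------------
# metric preparation
# ---------------------------------------------------------------------------

def _prepare(X: np.ndarray, metric: str) -> np.ndarray:
    """Map samples into the space in which distances are measured."""
    X = np.asarray(X, dtype=np.float64)
    if metric == "raw":
        return X
    if metric == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return (X - mu) / sd
    if metric == "mahalanobis":
        mu = X.mean(axis=0)
        Xc = X - mu
        cov = np.cov(Xc, rowvar=False)
        cov = np.atleast_2d(cov)
        vals, vecs = np.linalg.eigh(cov)
        floor = max(vals.max(), 1e-12) * 1e-12
        vals = np.maximum(vals, floor)
        return Xc @ vecs / np.sqrt(vals)[None, :]
    raise ValueError("metric must be 'mahalanobis', 'zscore' or 'raw'")


def scatter_matrices(table, feature_subset=None,
                     metric: str = "mahalanobis") -> ScatterPair:
    """Scatter matrices of a labeled feature table over a feature subset."""
    X0, X1 = _class_arrays(table, feature_subset)
    Z = _prepare(np.vstack([X0, X1]), metric)
    return _scatter_from_arrays(Z[: len(X0)], Z[len(X0):])


def _class_arrays(table, feature_subset=None):
    if isinstance(table, pd.DataFrame):
        if "label" not in table.columns:
            raise ValueError("feature table needs a 'label' column")
        labels = table["label"].to_numpy()
        cols = list(feature_subset) if feature_subset is not None else [
            c for c in table.columns if c != "label"]
        X = table[cols].to_numpy(dtype=np.float64)
    else:
        raise TypeError("expected a pandas DataFrame feature table")
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 classes required, got {uniq}")
    return X[labels == uniq[0]], X[labels == uniq[1]]


def criterion(pair: ScatterPair, method: str = "trace",
              ridge: float = RIDGE) -> float:
    """Scalar separability F from a scatter pair.

    ``trace`` gives trace(S_w^-1 S_b); ``det`` the determinant ratio.
    A relative ridge is added to S_w when it is poorly conditioned.
    """
    Sw, Sb = pair.Sw, pair.Sb
    d = Sw.shape[0]
    tr = np.trace(Sw)
    if tr <= 0 or not np.isfinite(tr):
        raise ValueError("within-class scatter is numerically zero")
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e10:
        logger.debug("ridge triggered on S_w (cond=%.3g)", cond)
        Sw = Sw + (ridge * tr / d) * np.eye(d)
    if method == "trace":
        return float(np.trace(np.linalg.solve(Sw, Sb)))
    if method == "det":
        sign, logdet_b = np.linalg.slogdet(Sb)
        if sign <= 0:
            return 0.0
        _, logdet_w = np.linalg.slogdet(Sw)
        return float(np.exp(logdet_b - logdet_w))
    raise ValueError("method must be 'trace' or 'det'")


def separability(table, feature_subset=None, metric: str = "mahalanobis",
                 method: str = "trace") -> float:
    """Convenience: criterion F of a feature subset of a labeled table."""
    return criterion(scatter_matrices(table, feature_subset, metric=metric),
                     method=method)


# ---------------------------------------------------------------------------
# floating stepwise search
# ---------------------------------------------------------------------------

def stepwise_select(table: pd.DataFrame, n_target: int,
                    metric: str = "mahalanobis", method: str = "trace",
                    floating: bool = True) -> SelectionTrace:
    """Sequential floating forward selection on the separability criterion.

    At each step the feature maximizing F of the augmented subset is added;
    afterwards, while removing a single feature (other than the one just
    added) strictly increases F, the best such feature is removed. Ties are
    broken by column order, making the search deterministic. The search stops
    when the subset reaches ``n_target`` features.
    """
    all_features = [c for c in table.columns if c != "label"]
    if len(all_features) < 2:
        raise ValueError("need at least 2 candidate features")
    if not (1 <= n_target <= len(all_features)):
        raise ValueError(f"n_target must be in [1, {len(all_features)}]")

    X0_full, X1_full = _class_arrays(table, all_features)
    col_index = {name: k for k, name in enumerate(all_features)}

    def F(subset: list[str]) -> float:
        idx = [col_index[s] for s in subset]
        Z = _prepare(np.vstack([X0_full[:, idx], X1_full[:, idx]]), metric)
        pair = _scatter_from_arrays(Z[: len(X0_full)], Z[len(X0_full):])
        try:
            return criterion(pair, method=method)
        except ValueError:
            # degenerate subset (e.g. a constant feature): no separability
            return -np.inf

    trace = SelectionTrace()
    selected: list[str] = []
    best_by_size: dict[int, float] = {}  # guards against add/remove cycles
    while len(selected) < n_target:
        candidates = [f for f in all_features if f not in selected]
        scores = [F(selected + [c]) for c in candidates]
        best_i = int(np.argmax(scores))
        just_added = candidates[best_i]
        selected.append(just_added)
        best_F = scores[best_i]
        best_by_size[len(selected)] = max(
            best_by_size.get(len(selected), -np.inf), best_F)
        trace.steps.append(("add", just_added, best_F))
        trace.criterion_values.append(best_F)
        if len(selected) == n_target:
            break
        # conditional exclusion: a removal must strictly improve on the
        # current subset *and* on the best subset seen at the smaller size
        while floating and len(selected) > 2:
            removable = [f for f in selected if f != just_added]
            drop_scores = [F([f for f in selected if f != r]) for r in removable]
            k = int(np.argmax(drop_scores))
            bar = max(best_F, best_by_size.get(len(selected) - 1, -np.inf))
            if drop_scores[k] > bar:
                removed = removable[k]
                selected.remove(removed)
                best_F = drop_scores[k]
                best_by_size[len(selected)] = best_F
                trace.steps.append(("remove", removed, best_F))
                trace.criterion_values.append(best_F)
            else:
                break
    trace.selected = selected
    return trace
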