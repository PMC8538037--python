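"""Elongation-based morphology classification.

Cells are sorted into the three canonical interstitial-cell morphology
classes on a single feature, the elongation x = 1 - width/length: low x is
myofibroblast-like (large stellate), intermediate x fibroblast-like, and
high x smooth-muscle-like (spindle). The published decision intervals are
0 < x < 0.551 (myFib), 0.551 < x < 0.817 (Fib) and 0.817 < x < 1 (SMc).

The classifier is a 1-D, 3-class k-medoids model. Because the data are
one-dimensional, clusters of the L1 k-medoids optimum are contiguous in
sorted order, so the global optimum is found exactly by dynamic programming
over contiguous 3-splits — no stochastic restarts. Soft class membership is
a distance softmax; cells whose top membership is not above 0.90 are
flagged as excluded from downstream per-class statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ElongationKMedoids",
    "ClassAssignment",
    "fit_classifier",
    "classify",
    "evaluate_accuracy",
    "class_composition",
    "default_model",
]

CLASS_ORDER = ("myFib", "Fib", "SMc")  # ascending elongation
MEMBERSHIP_CUTOFF = 0.90

#: Published decision boundaries for the frozen, no-fit model.
PUBLISHED_BOUNDARIES = (0.551, 0.817)


@dataclass
class ClassAssignment:
    cell_id: str
    predicted_class: str
    membership_prob: float
    included: bool


def _segment_cost(sorted_x: np.ndarray, prefix: np.ndarray, i: np.ndarray | int, j: int):
    """Total L1 deviation of sorted_x[i..j] from its medoid (lower median).

    Vectorized over the left endpoint i. prefix[t] = sum(sorted_x[:t]).
    """
    i = np.asarray(i)
    m = (i + j) // 2  # lower-median index: a valid L1 medoid
    xm = sorted_x[m]
    left = xm * (m - i + 1) - (prefix[m + 1] - prefix[i])
    right = (prefix[j + 1] - prefix[m + 1]) - xm * (j - m)
    return left + right


class ElongationKMedoids(BaseEstimator, ClusterMixin):
    """Exact 1-D k-medoids over elongation values, with soft membership.

    Parameters
    ----------
    n_clusters : int, default 3.
    membership_scale : float or "auto". Softness of the distance-softmax
        membership. "auto" uses the pooled within-class median absolute
        deviation from the assigned medoid.

    Attributes
    ----------
    medoids_ : (k,) ascending medoid elongations.
    boundaries_ : (k-1,) decision thresholds — midpoints between the extreme
        members of adjacent clusters.
    membership_scale_ : resolved softmax scale.
    classes_ : class names, ascending medoid (myFib, Fib, SMc for k = 3).
    labels_ : training-sample class indices.
    inertia_ : total L1 deviation at the optimum.
    """

    def __init__(self, n_clusters: int = 3, membership_scale: float | str = "auto"):
        self.n_clusters = n_clusters
        self.membership_scale = membership_scale

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if np.any(~np.isfinite(x)) or np.any((x < 0) | (x >= 1)):
            raise ValueError("elongations must be finite and lie in [0, 1)")
        k = self.n_clusters
        if len(np.unique(x)) < 3 * k:
            raise ValueError(f"need at least {3 * k} distinct values to fit {k} clusters")

        order = np.argsort(x, kind="stable")
        xs = x[order]
        n = len(xs)
        prefix = np.concatenate([[0.0], np.cumsum(xs)])

        # DP over contiguous splits: D[c][j] = optimal cost of xs[0..j] in c+1 clusters
        D_prev = np.array([_segment_cost(xs, prefix, 0, j) for j in range(n)])
        argsplit = np.zeros((k - 1, n), dtype=int)
        for c in range(1, k):
            D_cur = np.full(n, np.inf)
            for j in range(c, n):
                i = np.arange(c, j + 1)  # cluster c starts at i
                costs = D_prev[i - 1] + _segment_cost(xs, prefix, i, j)
                best = int(np.argmin(costs))
                D_cur[j] = costs[best]
                argsplit[c - 1, j] = i[best]
            D_prev = D_cur
        self.inertia_ = float(D_prev[n - 1])

        # backtrack segment starts
        starts = [0] * k
        j = n - 1
        for c in range(k - 1, 0, -1):
            starts[c] = int(argsplit[c - 1, j])
            j = starts[c] - 1
        bounds_idx = starts[1:]

        medoids, boundaries = [], []
        seg_edges = bounds_idx + [n]
        lo = 0
        labels_sorted = np.empty(n, dtype=int)
        for c, hi in enumerate(seg_edges):
            m = (lo + hi - 1) // 2
            medoids.append(xs[m])
            labels_sorted[lo:hi] = c
            if hi < n:
                boundaries.append(0.5 * (xs[hi - 1] + xs[hi]))
            lo = hi

        self.medoids_ = np.asarray(medoids)
        self.boundaries_ = np.asarray(boundaries)
        self.classes_ = np.asarray(CLASS_ORDER if k == 3 else [f"class{c}" for c in range(k)])
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        self.labels_ = labels

        if self.membership_scale == "auto":
            dev = np.abs(x - self.medoids_[labels])
            self.membership_scale_ = float(max(np.median(dev), 1e-6))
        else:
            self.membership_scale_ = float(self.membership_scale)
        return self

    # -- prediction ---------------------------------------------------------
    def _check_x(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        if np.any((x < 0) | (x >= 1)):
            raise ValueError("elongation must lie in [0, 1)")
        return x

    def predict(self, X) -> np.ndarray:
        """Hard class labels from the decision intervals."""
        check_is_fitted(self, "boundaries_")
        x = self._check_x(X)
        return self.classes_[np.searchsorted(self.boundaries_, x)]

    def predict_proba(self, X) -> np.ndarray:
        """Softmax membership over negative scaled distances to the medoids."""
        check_is_fitted(self, "medoids_")
        x = self._check_x(X)
        d = np.abs(x[:, None] - self.medoids_[None, :]) / self.membership_scale_
        w = np.exp(-(d - d.min(axis=1, keepdims=True)))
        return w / w.sum(axis=1, keepdims=True)

    def assign(self, X, cell_ids=None) -> pd.DataFrame:
        """Per-cell assignment table with the 90 % inclusion rule applied."""
        x = self._check_x(X)
        labels = self.predict(x)
        proba = self.predict_proba(x)
        # membership of the *predicted* (interval) class
        cls_idx = np.searchsorted(self.boundaries_, x)
        p = proba[np.arange(len(x)), cls_idx]
        if cell_ids is None:
            cell_ids = [f"cell-{i}" for i in range(len(x))]
        return pd.DataFrame(
            {
                "cell_id": cell_ids,
                "elongation": x,
                "predicted_class": labels,
                "membership_prob": p,
                "included": p > MEMBERSHIP_CUTOFF,
            }
        )

    # -- persistence ----------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "medoids_")
        return json.dumps(
            {
                "medoids": self.medoids_.tolist(),
                "boundaries": self.boundaries_.tolist(),
                "membership_scale": self.membership_scale_,
                "classes": list(map(str, self.classes_)),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ElongationKMedoids":
        d = json.loads(payload)
        model = cls(n_clusters=len(d["medoids"]))
        model.medoids_ = np.asarray(d["medoids"], float)
        model.boundaries_ = np.asarray(d["boundaries"], float)
        model.membership_scale_ = float(d["membership_scale"])
        model.classes_ = np.asarray(d["classes"])
        return model


def default_model(membership_scale: float = 0.05) -> ElongationKMedoids:
    """Frozen model with the published 0.551 / 0.817 boundaries (no fit).

    Medoids sit at the interval midpoints; use when no training elongations
    are available.
    """
    model = ElongationKMedoids()
    b1, b2 = PUBLISHED_BOUNDARIES
    model.boundaries_ = np.array([b1, b2])
    model.medoids_ = np.array([b1 / 2, (b1 + b2) / 2, (b2 + 1.0) / 2])
    model.membership_scale_ = membership_scale
    model.classes_ = np.asarray(CLASS_ORDER)
    return model


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_classifier(elongations, k: int = 3, membership_scale="auto") -> ElongationKMedoids:
    return ElongationKMedoids(n_clusters=k, membership_scale=membership_scale).fit(elongations)


def classify(x: float, model: ElongationKMedoids) -> ClassAssignment:
    row = model.assign([x]).iloc[0]
    return ClassAssignment(
        cell_id=row["cell_id"],
        predicted_class=row["predicted_class"],
        membership_prob=float(row["membership_prob"]),
        included=bool(row["included"]),
    )


def evaluate_accuracy(predicted, manual, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Agreement fraction and its bootstrap SD over cells.

    Raises if the two label sets share no classes (a symptom of comparing
    incompatible annotation schemes).
    """
    predicted = np.asarray(predicted)
    manual = np.asarray(manual)
    if len(predicted) != len(manual):
        raise ValueError("label lists must have equal length")
    if not set(predicted) & set(manual):
        raise ValueError("predicted and manual label sets are disjoint")
    agree = predicted == manual
    acc = float(agree.mean())
    rng = np.random.default_rng(seed)
    n = len(agree)
    boots = rng.choice(agree.astype(float), size=(n_boot, n), replace=True).mean(axis=1)
    return acc, float(boots.std(ddof=1))


def class_composition(assignments: pd.DataFrame, included_only: bool = True) -> pd.Series:
    """Percentage of cells per class (summing to 100) over included cells."""
    df = assignments[assignments["included"]] if included_only else assignments
    if len(df) == 0:
        raise ValueError("no included assignments")
    counts = df["predicted_class"].value_counts()
    pct = 100.0 * counts / counts.sum()
    return pct.reindex(CLASS_ORDER, fill_value=0.0)
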