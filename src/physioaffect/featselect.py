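"""Feature ranking by Kullback-Leibler divergence with an
information-gain convergence stopping rule.

Each normalized feature is summarised per class by a smoothed histogram
on [0, 1]; features are ranked by the divergence of the negative-emotion
distribution p from the basic-emotion distribution q (in bits). Features
are then added one-by-one in ranking order and the cumulative
information gain of the joint median-split partition is tracked; the
selection stops at the first index where the gain curve has flattened
(forward difference below half the maximum difference) after climbing to
within a quarter of its total range of the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .features import FEATURE_NAMES, labels_of


def estimate_distribution(
    values: np.ndarray, n_bins: int = 10, pseudo_count: float = 1.0
) -> np.ndarray:
    """Histogram probabilities on equal-width bins spanning [0, 1].

    Probabilities are Laplace-smoothed: (count + pseudo) / (n + n_bins·pseudo),
    so every bin stays strictly positive whenever ``pseudo_count > 0``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("values must lie in [0, 1]; normalize first")
    counts, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    return (counts + pseudo_count) / (v.size + n_bins * pseudo_count)


def kld(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence Σ p·log2(p/q), in bits; 0·log0 = 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must share bin edges")
    if np.any(q <= 0):
        raise ValueError("q has empty bins; use a positive pseudo-count")
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy of the class proportions, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label set")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _median_binarize(X: np.ndarray) -> np.ndarray:
    """Binarize each column at its pooled median (strictly above → 1)."""
    return (X > np.median(X, axis=0)).astype(np.int8)


def cumulative_ig(
    X: np.ndarray, y: np.ndarray, ranking: np.ndarray, k: int
) -> float:
    """Information gain of the joint median-split partition of the top-k features.

    The top-k ranked features are binarized at their pooled medians; the
    partition cells are the nonempty joint bit patterns, and the gain is
    H(S) minus the cell-weighted label entropy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}]")
    bits = _median_binarize(X[:, np.asarray(ranking)[:k]])
    _, cell = np.unique(bits, axis=0, return_inverse=True)
    h_s = entropy(y)
    n = len(y)
    h_cond = 0.0
    for c in np.unique(cell):
        m = cell == c
        h_cond += (m.sum() / n) * entropy(y[m])
    return h_s - h_cond


def convergence_point(ig_curve: np.ndarray) -> tuple[int, float]:
    """Stopping index k* on a cumulative information-gain curve.

    CP = ¼·(max IG − min IG). k* is the smallest k whose forward
    difference drops below half the maximum forward difference and whose
    IG_k has climbed to within CP of the curve maximum (the curve has
    both flattened and nearly reached its ceiling); if no index
    qualifies, all features are kept (k* = d). A perfectly flat curve
    yields k* = 1. Returns (k*, CP).
    """
    ig = np.asarray(ig_curve, dtype=float)
    if ig.size < 2:
        raise ValueError("curve needs at least 2 points")
    cp = 0.25 * (ig.max() - ig.min())
    diffs = np.diff(ig)
    max_diff = diffs.max()
    if max_diff <= 0:
        return 1, cp
    floor = ig.max() - cp
    for k in range(1, len(ig)):  # k indexes IG_k (1-based); diff_k = IG_{k+1} - IG_k
        if diffs[k - 1] < 0.5 * max_diff and ig[k - 1] >= floor:
            return k, cp
    return len(ig), cp


class KLDivergenceSelector(SelectorMixin, BaseEstimator):
    """Rank features by class-conditional KL divergence and cut at the
    information-gain convergence point.

    Parameters
    ----------
    n_bins : int
        Histogram bins on [0, 1] for the per-class distributions.
    pseudo_count : float
        Laplace smoothing added to every bin (keeps q strictly positive).
    positive_label : int
        The class treated as p (negative emotion); the other class is q.

    Attributes (after fit)
    ----------------------
    kld_ : per-feature divergence in bits.
    ranking_ : feature indices in descending divergence order.
    ig_curve_ : cumulative information gain as ranked features are added.
    k_ : convergence index (number of features kept).
    cp_ : the convergence-point offset ¼·(max IG − min IG).
    """

    def __init__(self, n_bins: int = 10, pseudo_count: float = 1.0,
                 positive_label: int = 1):
        self.n_bins = n_bins
        self.pseudo_count = pseudo_count
        self.positive_label = positive_label

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("selector requires exactly two classes")
        if self.positive_label not in classes:
            raise ValueError("positive_label absent from y")
        pos = y == self.positive_label
        self.kld_ = np.array([
            kld(
                estimate_distribution(X[pos, j], self.n_bins, self.pseudo_count),
                estimate_distribution(X[~pos, j], self.n_bins, self.pseudo_count),
            )
            for j in range(X.shape[1])
        ])
        # stable sort so ties keep original feature order
        self.ranking_ = np.argsort(-self.kld_, kind="stable")
        d = X.shape[1]
        self.ig_curve_ = np.array(
            [cumulative_ig(X, y, self.ranking_, k) for k in range(1, d + 1)]
        )
        if d == 1:
            self.k_, self.cp_ = 1, 0.0
        else:
            self.k_, self.cp_ = convergence_point(self.ig_curve_)
        self.n_features_in_ = d
        self.entropy_ = entropy(y)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[: self.k_]] = True
        return mask


@dataclass
class SelectedFeatureSet:
    """Selection diagnostics: ranking, divergences, gain curve and the cut."""

    ordered_names: list[str]
    kld_values: dict[str, float]
    ig_curve: np.ndarray
    entropy: float
    cp: float
    k: int
    selected: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.selected = self.ordered_names[: self.k]

    def to_dict(self) -> dict:
        return {
            "ranking": self.ordered_names,
            "kld_bits": {n: float(v) for n, v in self.kld_values.items()},
            "ig_curve_bits": [float(v) for v in self.ig_curve],
            "entropy_bits": float(self.entropy),
            "cp": float(self.cp),
            "k": int(self.k),
            "selected": self.selected,
        }


def select_features(
    matrix: pd.DataFrame,
    labels: np.ndarray | None = None,
    n_bins: int = 10,
    pseudo_count: float = 1.0,
    feature_names: list[str] | None = None,
) -> SelectedFeatureSet:
    """Run the full selector on a normalized feature matrix."""
    names = feature_names or [c for c in FEATURE_NAMES if c in matrix.columns]
    X = matrix[names].to_numpy(dtype=float)
    y = labels_of(matrix) if labels is None else np.asarray(labels)
    sel = KLDivergenceSelector(n_bins=n_bins, pseudo_count=pseudo_count).fit(X, y)
    ordered = [names[i] for i in sel.ranking_]
    return SelectedFeatureSet(
        ordered_names=ordered,
        kld_values={names[i]: sel.kld_[i] for i in sel.ranking_},
        ig_curve=sel.ig_curve_,
        entropy=sel.entropy_,
        cp=sel.cp_,
        k=sel.k_,
    )
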