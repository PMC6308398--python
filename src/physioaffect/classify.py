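"""Classifiers and leave-one-out evaluation.

The primary classifier is a one-hidden-layer perceptron with sigmoid
activations throughout, trained by full-batch gradient descent on
binary cross-entropy at a fixed learning rate of 0.01 for exactly 2000
iterations; the hidden width defaults to one less than the input
dimension. Linear and quadratic Gaussian discriminants with equal
priors serve as comparators. Performance is measured by leave-one-out
cross-validation and summarised as accuracy, sensitivity, specificity,
PPV and NPV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .outliers import ClassGaussian, fit_class_gaussian, mahalanobis_sq


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class NegativeEmotionMLP(ClassifierMixin, BaseEstimator):
    """One-hidden-layer sigmoid perceptron for binary emotion labels.

    Parameters
    ----------
    hidden_nodes : int or None
        Hidden width; ``None`` means input dimension − 1 (floor 1).
    learning_rate : float
        Fixed step size for full-batch gradient descent.
    n_iter : int
        Exact number of weight updates (no early stopping).
    random_state : int
        Seed for the uniform(−0.5, 0.5) weight initialization.

    Deterministic: identical (X, y, params, seed) give bit-identical
    weights. A predicted probability of exactly 0.5 maps to the positive
    (negative-emotion) class.
    """

    def __init__(self, hidden_nodes: int | None = None, learning_rate: float = 0.01,
                 n_iter: int = 2000, random_state: int = 0):
        self.hidden_nodes = hidden_nodes
        self.learning_rate = learning_rate
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("training labels must contain both classes")
        t = (y == self.classes_[1]).astype(float)
        n, d = X.shape
        h = self.hidden_nodes if self.hidden_nodes is not None else max(d - 1, 1)
        if h < 1:
            raise ValueError("hidden_nodes must be at least 1")
        rng = np.random.default_rng(self.random_state)
        w1 = rng.uniform(-0.5, 0.5, size=(d, h))
        b1 = rng.uniform(-0.5, 0.5, size=h)
        w2 = rng.uniform(-0.5, 0.5, size=h)
        b2 = rng.uniform(-0.5, 0.5)
        lr = self.learning_rate
        for _ in range(self.n_iter):
            hid = _sigmoid(X @ w1 + b1)
            out = _sigmoid(hid @ w2 + b2)
            # BCE gradient, summed over the batch
            delta_out = out - t
            grad_w2 = hid.T @ delta_out
            grad_b2 = delta_out.sum()
            delta_hid = np.outer(delta_out, w2) * hid * (1.0 - hid)
            grad_w1 = X.T @ delta_hid
            grad_b1 = delta_hid.sum(axis=0)
            w2 -= lr * grad_w2
            b2 -= lr * grad_b2
            w1 -= lr * grad_w1
            b1 -= lr * grad_b1
        self.coefs_ = [w1, w2]
        self.intercepts_ = [b1, b2]
        self.n_features_in_ = d
        self.hidden_nodes_ = h
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension does not match training data")
        hid = _sigmoid(X @ self.coefs_[0] + self.intercepts_[0])
        p1 = _sigmoid(hid @ self.coefs_[1] + self.intercepts_[1])
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return np.where(p1 >= 0.5, self.classes_[1], self.classes_[0])


class GaussianDiscriminant(ClassifierMixin, BaseEstimator):
    """Gaussian discriminant with equal priors: pooled covariance (LDA)
    or one covariance per class (QDA), ridge-regularized."""

    def __init__(self, shared_covariance: bool = True, ridge: float = 1e-6):
        self.shared_covariance = shared_covariance
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        counts = np.array([np.sum(y == c) for c in self.classes_])
        if np.any(counts < 2):
            raise ValueError("each class needs at least 2 samples")
        per_class = {c: fit_class_gaussian(X[y == c], self.ridge) for c in self.classes_}
        if self.shared_covariance:
            n = len(y)
            pooled = sum(
                (counts[i] - 1) * per_class[c].cov
                for i, c in enumerate(self.classes_)
            ) / (n - len(self.classes_))
            per_class = {
                c: ClassGaussian(mean=g.mean, cov=pooled, ridge=g.ridge)
                for c, g in per_class.items()
            }
        self.gaussians_ = per_class
        self.n_features_in_ = X.shape[1]
        return self

    def _log_posteriors(self, X) -> np.ndarray:
        check_is_fitted(self, "gaussians_")
        X = check_array(X)
        cols = []
        for c in self.classes_:
            g = self.gaussians_[c]
            _, logdet = np.linalg.slogdet(g.cov)
            cols.append(-0.5 * (mahalanobis_sq(X, g) + logdet))
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        lp = self._log_posteriors(X)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posteriors(X), axis=1)]


def train_mlp(X, y, hidden_nodes=None, learning_rate=0.01, n_iter=2000, seed=0):
    """Fit the sigmoid MLP (thin functional wrapper)."""
    return NegativeEmotionMLP(hidden_nodes, learning_rate, n_iter, seed).fit(X, y)


def train_lda(X, y, ridge: float = 1e-6) -> GaussianDiscriminant:
    return GaussianDiscriminant(shared_covariance=True, ridge=ridge).fit(X, y)


def train_qda(X, y, ridge: float = 1e-6) -> GaussianDiscriminant:
    return GaussianDiscriminant(shared_covariance=False, ridge=ridge).fit(X, y)


@dataclass
class ConfusionCounts:
    """Binary confusion table; positive class = negative emotion (label 1)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV as fractions.

    A metric with a zero denominator is reported as NaN with a warning.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "sensitivity": ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": ratio(c.tn, c.fp + c.tn, "specificity"),
        "ppv": ratio(c.tp, c.tp + c.fp, "PPV"),
        "npv": ratio(c.tn, c.fn + c.tn, "NPV"),
    }


@dataclass
class EvaluationReport:
    """LOOCV outcome for one classifier."""

    classifier: str
    confusion: ConfusionCounts
    metrics: dict[str, float]
    n_folds: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "confusion": {
                "TP": int(self.confusion.tp), "TN": int(self.confusion.tn),
                "FP": int(self.confusion.fp), "FN": int(self.confusion.fn),
            },
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "metrics_percent": {k: round(100 * float(v), 2) for k, v in self.metrics.items()},
            "n_folds": int(self.n_folds),
            "config": {k: (v.item() if isinstance(v, np.generic) else v)
                       for k, v in self.config.items()},
        }


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    estimator: BaseEstimator,
    base_seed: int = 0,
    name: str | None = None,
) -> EvaluationReport:
    """Leave-one-out cross-validation with per-fold seeds base + fold index.

    If a fold's training labels collapse to a single class, that fold
    predicts the majority (prior) class with a warning. Confusion counts
    are aggregated over all n folds; label 1 is the positive class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples for LOOCV")
    counts = ConfusionCounts()
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if np.unique(y_tr).size < 2:
            warnings.warn(f"fold {i}: single-class training set; predicting the prior")
            vals, cnts = np.unique(y_tr, return_counts=True)
            pred = vals[np.argmax(cnts)]
        else:
            est = clone(estimator)
            if "random_state" in est.get_params():
                est.set_params(random_state=base_seed + i)
            est.fit(X_tr, y_tr)
            pred = est.predict(X[i: i + 1])[0]
        truth = y[i]
        if truth == 1:
            counts.tp += int(pred == 1)
            counts.fn += int(pred != 1)
        else:
            counts.tn += int(pred != 1)
            counts.fp += int(pred == 1)
    return EvaluationReport(
        classifier=name or type(estimator).__name__,
        confusion=counts,
        metrics=metrics_from_confusion(counts),
        n_folds=n,
        config=estimator.get_params(),
    )
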