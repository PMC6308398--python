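"""Per-class Mahalanobis outlier removal.

Each emotion class is modelled as a multivariate Gaussian fitted on its
own feature vectors; windows whose squared Mahalanobis distance from
their class centre exceeds a chi-square quantile (df = feature
dimension) are treated as artifacts or non-induced-emotion segments and
removed. Under multivariate normality the squared distance is
chi-square distributed, so the quantile directly calibrates the
expected removal rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FEATURE_NAMES, labels_of

RIDGE_LAMBDA = 1e-6


@dataclass
class ClassGaussian:
    """Sample mean and ridge-regularized covariance of one class."""

    mean: np.ndarray
    cov: np.ndarray
    ridge: float

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)


def fit_class_gaussian(rows: np.ndarray, ridge: float = RIDGE_LAMBDA) -> ClassGaussian:
    """Fit mean and covariance; a ridge of ``ridge * trace(Σ)/d`` (or ``ridge``
    itself for an all-zero covariance) is added to the diagonal so the
    covariance is always invertible."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a class Gaussian")
    mean = rows.mean(axis=0)
    cov = np.cov(rows, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    tr = np.trace(cov)
    eps = ridge * (tr / d if tr > 0 else 1.0)
    cov = cov + eps * np.eye(d)
    return ClassGaussian(mean=mean, cov=cov, ridge=eps)


def mahalanobis_sq(x: np.ndarray, g: ClassGaussian) -> np.ndarray:
    """Squared Mahalanobis distance (x − µ)ᵀ Σ⁻¹ (x − µ); vectorized over rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != g.mean.shape[0]:
        raise ValueError("dimension mismatch")
    delta = x - g.mean
    d2 = np.einsum("ij,jk,ik->i", delta, g.precision, delta)
    return np.maximum(d2, 0.0)


class MahalanobisOutlierRemover(BaseEstimator, OutlierMixin):
    """Flag feature vectors far from their class Gaussian.

    Parameters
    ----------
    quantile : float
        Chi-square quantile (df = n_features) defining the keep threshold.
    per_class : bool
        Fit one Gaussian per class (default) or a single pooled Gaussian.
    ridge : float
        Relative ridge added to the covariance diagonal.

    After ``fit(X, y)``, ``decision_function`` returns ``threshold_ −
    squared distance`` (negative = outlier) and ``predict`` the usual
    sklearn convention (+1 inlier, −1 outlier).
    """

    def __init__(self, quantile: float = 0.975, per_class: bool = True,
                 ridge: float = RIDGE_LAMBDA):
        self.quantile = quantile
        self.per_class = per_class
        self.ridge = ridge

    def fit(self, X, y=None):
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie strictly between 0 and 1")
        X = check_array(X)
        if self.per_class:
            if y is None:
                raise ValueError("per-class fitting requires labels")
            y = np.asarray(y)
            self.gaussians_ = {c: fit_class_gaussian(X[y == c], self.ridge)
                               for c in np.unique(y)}
        else:
            self.gaussians_ = {None: fit_class_gaussian(X, self.ridge)}
        self.n_features_in_ = X.shape[1]
        self.threshold_ = float(stats.chi2.ppf(self.quantile, df=X.shape[1]))
        return self

    def score_samples(self, X, y=None) -> np.ndarray:
        """Squared Mahalanobis distance of each row from its class centre."""
        check_is_fitted(self, "gaussians_")
        X = check_array(X)
        if self.per_class:
            if y is None:
                raise ValueError("per-class scoring requires labels")
            y = np.asarray(y)
            d2 = np.empty(len(X))
            for c, g in self.gaussians_.items():
                m = y == c
                if m.any():
                    d2[m] = mahalanobis_sq(X[m], g)
            return d2
        return mahalanobis_sq(X, self.gaussians_[None])

    def decision_function(self, X, y=None) -> np.ndarray:
        return self.threshold_ - self.score_samples(X, y)

    def predict(self, X, y=None) -> np.ndarray:
        return np.where(self.decision_function(X, y) >= 0, 1, -1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).predict(X, y)


@dataclass
class OutlierMask:
    """Per-row keep flag, squared distance, and the threshold applied."""

    keep: np.ndarray
    distance_sq: np.ndarray
    threshold: float

    @property
    def n_removed(self) -> int:
        return int(np.sum(~self.keep))


def remove_outliers(
    matrix: pd.DataFrame, quantile: float = 0.975, per_class: bool = True
) -> tuple[pd.DataFrame, OutlierMask]:
    """Drop windows whose squared distance exceeds the chi-square threshold.

    Convenience wrapper over :class:`MahalanobisOutlierRemover` operating
    on a feature matrix with metadata columns.
    """
    X = matrix[FEATURE_NAMES].to_numpy(dtype=float)
    y = labels_of(matrix)
    est = MahalanobisOutlierRemover(quantile=quantile, per_class=per_class).fit(X, y)
    d2 = est.score_samples(X, y)
    keep = d2 <= est.threshold_
    mask = OutlierMask(keep=keep, distance_sq=d2, threshold=est.threshold_)
    return matrix.loc[keep].reset_index(drop=True), mask
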