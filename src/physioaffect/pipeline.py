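"""End-to-end pipeline: extract → normalize → clean → select → evaluate.

Normalization bounds, the outlier threshold and the feature selection
are fitted once on a subject's full 200-window set, mirroring the
per-subject customization workflow; this leaks selection information
into the leave-one-out folds, which is documented, and a ``strict_cv``
mode refits the selector inside every fold for comparison.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .classify import (
    ConfusionCounts,
    EvaluationReport,
    GaussianDiscriminant,
    NegativeEmotionMLP,
    loocv,
    metrics_from_confusion,
)
from .features import FEATURE_NAMES, WindowSpec, build_feature_matrix, labels_of, normalize_minmax
from .featselect import KLDivergenceSelector, select_features
from .outliers import remove_outliers
from .signals import Recording

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    window: WindowSpec = field(default_factory=WindowSpec)
    outlier_quantile: float = 0.975
    n_bins: int = 10
    pseudo_count: float = 1.0
    learning_rate: float = 0.01
    n_iter: int = 2000
    classifiers: tuple[str, ...] = ("nn", "lda", "qda")
    strict_cv: bool = False
    seed: int = 0


def _make_estimator(kind: str, n_features: int, cfg: PipelineConfig):
    if kind == "nn":
        return NegativeEmotionMLP(
            hidden_nodes=max(n_features - 1, 1),
            learning_rate=cfg.learning_rate,
            n_iter=cfg.n_iter,
            random_state=cfg.seed,
        )
    if kind == "lda":
        return GaussianDiscriminant(shared_covariance=True)
    if kind == "qda":
        return GaussianDiscriminant(shared_covariance=False)
    raise ValueError(f"unknown classifier {kind!r}")


def _strict_loocv(X, y, kind: str, cfg: PipelineConfig) -> EvaluationReport:
    """LOOCV that refits the KLD selector on each fold's training rows."""
    n = len(y)
    counts = ConfusionCounts()
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sel = KLDivergenceSelector(n_bins=cfg.n_bins, pseudo_count=cfg.pseudo_count)
        X_tr = sel.fit_transform(X[mask], y[mask])
        est = _make_estimator(kind, X_tr.shape[1], cfg)
        if "random_state" in est.get_params():
            est.set_params(random_state=cfg.seed + i)
        est.fit(X_tr, y[mask])
        pred = est.predict(sel.transform(X[i: i + 1]))[0]
        if y[i] == 1:
            counts.tp += int(pred == 1)
            counts.fn += int(pred != 1)
        else:
            counts.tn += int(pred != 1)
            counts.fp += int(pred == 1)
    return EvaluationReport(
        classifier=f"{kind}:strict",
        confusion=counts,
        metrics=metrics_from_confusion(counts),
        n_folds=n,
        config={"strict_cv": True},
    )


def evaluate_matrix(
    matrix: pd.DataFrame, cfg: PipelineConfig | None = None
) -> dict:
    """Clean, select and LOOCV-evaluate an already-normalized feature matrix."""
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    cleaned, mask = remove_outliers(matrix, quantile=cfg.outlier_quantile)
    log.info("outlier removal: %d of %d rows removed", mask.n_removed, len(matrix))

    selection = select_features(
        cleaned, n_bins=cfg.n_bins, pseudo_count=cfg.pseudo_count
    )
    log.info("selected %d features: %s", selection.k, selection.selected)

    X_all = cleaned[FEATURE_NAMES].to_numpy(dtype=float)
    X_sel = cleaned[selection.selected].to_numpy(dtype=float)
    y = labels_of(cleaned)

    reports = {}
    for kind in cfg.classifiers:
        if cfg.strict_cv:
            rep = _strict_loocv(X_all, y, kind, cfg)
        else:
            est = _make_estimator(kind, X_sel.shape[1], cfg)
            rep = loocv(X_sel, y, est, base_seed=cfg.seed, name=kind)
        reports[kind] = rep
        log.info("%s LOOCV accuracy %.3f", kind, rep.metrics["accuracy"])

    return {
        "n_rows_input": int(len(matrix)),
        "n_outliers_removed": int(mask.n_removed),
        "selection": selection.to_dict(),
        "reports": {k: r.to_dict() for k, r in reports.items()},
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }


def run_pipeline(
    recordings: dict[str, Recording] | pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Full pipeline from raw recordings (or a pre-extracted feature matrix).

    Returns one JSON-serialisable report with the normalized matrix's
    provenance, outlier log, selection diagnostics and per-classifier
    LOOCV metrics.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(recordings, pd.DataFrame):
        matrix = recordings
    else:
        matrix = build_feature_matrix(recordings, cfg.window)
    normalized, bounds = normalize_minmax(matrix)
    report = evaluate_matrix(normalized, cfg)
    report["normalization_bounds"] = bounds.to_dict()
    report["config"] = {
        "window": asdict(cfg.window),
        "outlier_quantile": cfg.outlier_quantile,
        "n_bins": cfg.n_bins,
        "pseudo_count": cfg.pseudo_count,
        "learning_rate": cfg.learning_rate,
        "n_iter": cfg.n_iter,
        "classifiers": list(cfg.classifiers),
        "strict_cv": cfg.strict_cv,
        "seed": cfg.seed,
    }
    return report
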