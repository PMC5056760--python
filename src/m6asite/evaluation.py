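"""Performance evaluation: confusion metrics, ROC/PR curves, CV.

Conventions:

* sensitivity = TP / (TP + FN), specificity = TN / (TN + FP),
  MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
  a zero denominator returns 0.0;
* AUROC is the rank statistic (tied scores counted half), which equals
  the trapezoidal area under the empirical ROC curve;
* AUPR is the step-wise, non-interpolated summation over descending
  score thresholds (average precision);
* cross-validation uses stratified folds, pools the out-of-fold scores
  into a single ROC/PR, and refits the scaler and the hyperparameter
  search inside every training fold so no information leaks from the
  held-out part.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    TrainedPredictor,
    apply_scaler,
    fit_scaler,
    grid_search,
)


# ---------------------------------------------------------------------------
# confusion-matrix metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0.0 when there are no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); 0.0 when there are no negatives."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when the denominator is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Counts for the rule "predict positive iff score >= threshold"."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


# ---------------------------------------------------------------------------
# curves

def _check_both_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to compute a ROC curve")


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) of the empirical ROC; starts at (0,0),
    ends at (1,1)."""
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, thr


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the rank statistic (ties get 1/2)."""
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(precision, recall, thresholds) of the precision-recall curve."""
    labels = np.asarray(labels, dtype=int)
    if not np.any(labels == 1):
        raise ValueError("need at least one positive to compute a PR curve")
    precision, recall, thr = precision_recall_curve(
        labels, np.asarray(scores, dtype=float)
    )
    return precision, recall, thr


def aupr(scores, labels) -> float:
    """Area under the PR curve (non-interpolated average precision)."""
    labels = np.asarray(labels, dtype=int)
    if not np.any(labels == 1):
        raise ValueError("need at least one positive to compute AUPR")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# reports

@dataclass
class EvaluationReport:
    """Curves, areas and (optionally) per-stringency-level metrics."""

    n_pos: int
    n_neg: int
    auroc: float
    aupr: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    pr_precision: np.ndarray
    pr_recall: np.ndarray
    pr_thresholds: np.ndarray
    threshold_metrics: Optional[dict] = None  # level -> metric dict
    extras: dict = field(default_factory=dict)

    @property
    def ratio(self) -> float:
        return self.n_neg / self.n_pos if self.n_pos else float("inf")

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "threshold_metrics": self.threshold_metrics,
            "extras": self.extras,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def curves_to_tsv(self, prefix: Union[str, Path]) -> None:
        import pandas as pd

        prefix = str(prefix)
        pd.DataFrame(
            {"fpr": self.roc_fpr, "tpr": self.roc_tpr}
        ).to_csv(prefix + ".roc.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"recall": self.pr_recall, "precision": self.pr_precision}
        ).to_csv(prefix + ".pr.tsv", sep="\t", index=False)

    def plot(self, path: Union[str, Path]) -> None:
        """ROC and PR curves side by side (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(self.roc_fpr, self.roc_tpr)
        ax1.plot([0, 1], [0, 1], ls="--", c="grey")
        ax1.set(xlabel="false positive rate", ylabel="true positive rate",
                title=f"ROC (AUROC = {self.auroc:.3f})")
        ax2.plot(self.pr_recall, self.pr_precision)
        ax2.set(xlabel="recall", ylabel="precision",
                title=f"PR (AUPR = {self.aupr:.3f})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: Optional[dict] = None,
) -> EvaluationReport:
    """Full report from raw scores.

    ``thresholds`` maps stringency level -> decision threshold; when
    given, sensitivity / specificity / MCC are reported at each level.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    fpr, tpr, roc_thr = roc_points(scores, labels)
    precision, recall, pr_thr = pr_points(scores, labels)
    threshold_metrics = None
    if thresholds is not None:
        threshold_metrics = {}
        for level, thr in thresholds.items():
            c = confusion_at_threshold(scores, labels, thr)
            threshold_metrics[level] = {
                "threshold": float(thr),
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "sensitivity": sensitivity(c),
                "specificity": specificity(c),
                "mcc": mcc(c),
            }
    return EvaluationReport(
        n_pos=int(np.sum(labels == 1)),
        n_neg=int(np.sum(labels == 0)),
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_thresholds=roc_thr,
        pr_precision=precision,
        pr_recall=recall,
        pr_thresholds=pr_thr,
        threshold_metrics=threshold_metrics,
    )


def evaluate_independent(
    predictor: TrainedPredictor, X_test: np.ndarray, y_test: np.ndarray
) -> EvaluationReport:
    """Report on an untouched test set, including per-level metrics."""
    scores = predictor.score(np.asarray(X_test, dtype=float))
    thresholds = None
    if predictor.thresholds is not None:
        thresholds = {
            lv: predictor.thresholds.threshold(lv)
            for lv in predictor.thresholds.levels
        }
    report = evaluate_scores(scores, y_test, thresholds=thresholds)
    report.extras["mode"] = predictor.mode
    report.extras["taxon"] = predictor.taxon
    return report


# ---------------------------------------------------------------------------
# cross-validation

@dataclass(frozen=True)
class CVConfig:
    """Per-fold pipeline configuration for cross-validation.

    With ``C``/``gamma`` set, each fold fits the SVM directly; when
    either is None a grid search (on ``C_grid`` x ``gamma_grid`` with
    ``grid_folds`` inner folds) runs inside every training fold.
    """

    mode: str = "mature"
    C: Optional[float] = None
    gamma: Optional[float] = None
    C_grid: Sequence[float] = DEFAULT_C_GRID
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID
    grid_folds: int = 3


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    config: CVConfig = CVConfig(),
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold CV with pooled out-of-fold scores.

    Every record is scored exactly once by a model that never saw it;
    the pooled scores give a single ROC/PR.  Scaling and (if enabled)
    the grid search are refit inside each training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_both_classes(y)
    class_min = int(np.bincount(y).min())
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > class_min:
        raise ValueError(
            f"k={k} exceeds the size of the smaller class ({class_min})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(len(y))
    chosen = []
    for tr, te in skf.split(X, y):
        if config.C is None or config.gamma is None:
            C, gamma = grid_search(
                X[tr], y[tr],
                C_grid=config.C_grid, gamma_grid=config.gamma_grid,
                k_folds=config.grid_folds, seed=seed,
            )
        else:
            C, gamma = config.C, config.gamma
        chosen.append((C, gamma))
        scaler = fit_scaler(X[tr])
        from sklearn.svm import SVC

        svc = SVC(kernel="rbf", C=C, gamma=gamma)
        svc.fit(apply_scaler(scaler, X[tr]), y[tr])
        oof[te] = svc.decision_function(apply_scaler(scaler, X[te]))
    report = evaluate_scores(oof, y)
    report.extras["cv"] = {"k": k, "hyperparameters_per_fold": chosen}
    return report
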