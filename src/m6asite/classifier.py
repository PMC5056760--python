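"""RBF-kernel SVM classification of candidate m6A sites.

The pipeline is: per-feature standardization (fit on the training
matrix only), an RBF-kernel support vector machine whose hyperparameters
(C, gamma) are chosen by grid search maximizing cross-validated AUROC,
and a table of decision-score thresholds calibrated to target
specificities.  The ranking score of a site is the signed SVM decision
value: larger means more likely methylated.

Three confidence levels are exposed, mirroring common reporting
practice for site predictors: high / moderate / low stringency map to
decreasing target specificities (mature mode 90.0 / 85.2 / 80.0 %,
full-transcript mode 93.0 / 88.0 / 83.0 %).  A site is "predicted" at
a level iff its score is at least that level's threshold, so the
predicted-site sets are nested across levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__ as _PKG_VERSION
from .features import N_SHUFFLES, assemble_matrix, feature_dim, feature_layout
from .sequences import CandidateSite, Transcript, scan_drach

MODEL_FORMAT = "m6asite-model"
MODEL_VERSION = 1

LEVELS = ("high", "moderate", "low")

#: default target specificities per mode and stringency level
DEFAULT_TARGET_SPECIFICITIES = {
    "mature": {"high": 0.900, "moderate": 0.852, "low": 0.800},
    "full": {"high": 0.930, "moderate": 0.880, "low": 0.830},
}

#: default hyperparameter grids (log2 steps of 2, i.e. factors of 4)
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))

#: optimizer stopping tolerance for the final fit; tight enough that the
#: fitted decision function is invariant (to ~1e-7) under permutation of
#: training-row order, whose ordering libsvm is otherwise sensitive to
SVC_TOL = 1e-6


class ModelFormatError(ValueError):
    """Raised when a model file is unreadable or incompatible."""


# ---------------------------------------------------------------------------
# feature scaling

@dataclass(frozen=True)
class FeatureScaler:
    """Per-column standardization fitted on training data.

    Columns with zero training standard deviation pass through
    unchanged (no centering), so constant blocks such as all-zero
    one-hot bits do not inject NaNs.
    """

    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.mean)


def fit_scaler(matrix: np.ndarray) -> FeatureScaler:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training rows")
    return FeatureScaler(mean=matrix.mean(axis=0), sd=matrix.std(axis=0, ddof=0))


def apply_scaler(scaler: FeatureScaler, matrix: np.ndarray) -> np.ndarray:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] != scaler.n_features:
        raise ValueError(
            f"dimension mismatch: scaler has {scaler.n_features} features, "
            f"matrix has {matrix.shape[1]}"
        )
    live = scaler.sd > 0
    out = matrix.copy()
    out[:, live] = (matrix[:, live] - scaler.mean[live]) / scaler.sd[live]
    return out


def invert_scaler(scaler: FeatureScaler, matrix: np.ndarray) -> np.ndarray:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    live = scaler.sd > 0
    out = matrix.copy()
    out[:, live] = matrix[:, live] * scaler.sd[live] + scaler.mean[live]
    return out


# ---------------------------------------------------------------------------
# hyperparameter search

def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (C, gamma) maximizing mean cross-validated AUROC.

    Ties are broken toward smaller C, then smaller gamma.  Folds whose
    held-out part contains a single class are skipped with a warning;
    if every fold is degenerate the search fails.
    """
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn("skipping a cross-validation fold with a single class")
            continue
        folds.append((tr, te))
    if not folds:
        raise ValueError("all cross-validation folds are single-class")

    best: Optional[tuple] = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            aucs = []
            for tr, te in folds:
                scaler = fit_scaler(X[tr])
                svc = SVC(kernel="rbf", C=C, gamma=gamma)
                svc.fit(apply_scaler(scaler, X[tr]), y[tr])
                scores = svc.decision_function(apply_scaler(scaler, X[te]))
                aucs.append(roc_auc_score(y[te], scores))
            mean_auc = float(np.mean(aucs))
            if best is None or mean_auc > best[0]:
                best = (mean_auc, C, gamma)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# threshold calibration

@dataclass(frozen=True)
class ThresholdEntry:
    threshold: float
    achieved_specificity: float
    target_specificity: float


@dataclass(frozen=True)
class ThresholdTable:
    """Decision thresholds per stringency level (high > moderate > low)."""

    entries: dict  # level -> ThresholdEntry

    def __post_init__(self) -> None:
        specs = [self.entries[lv].target_specificity
                 for lv in LEVELS if lv in self.entries]
        if any(later >= earlier for earlier, later in zip(specs, specs[1:])):
            raise ValueError(
                "target specificities must strictly decrease from high to low"
            )

    def threshold(self, level: str) -> float:
        return self.entries[level].threshold

    @property
    def levels(self) -> tuple:
        return tuple(lv for lv in LEVELS if lv in self.entries)

    def to_dict(self) -> dict:
        return {
            lv: {
                "threshold": e.threshold,
                "achieved_specificity": e.achieved_specificity,
                "target_specificity": e.target_specificity,
            }
            for lv, e in self.entries.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdTable":
        return cls(
            {
                lv: ThresholdEntry(
                    v["threshold"], v["achieved_specificity"], v["target_specificity"]
                )
                for lv, v in d.items()
            }
        )


def threshold_for_specificity(neg_scores: np.ndarray, target: float) -> float:
    """Smallest decision threshold whose empirical specificity on the
    calibration negatives is >= target (predict positive iff score >= t)."""
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    n = len(neg)
    if n == 0:
        raise ValueError("calibration set contains no negatives")
    need = math.ceil(target * n - 1e-12)  # negatives strictly below t
    if need <= 0:
        return float(neg[0])
    uniq = np.unique(neg)
    below = np.searchsorted(neg, uniq, side="left")  # count < each candidate
    ok = np.nonzero(below >= need)[0]
    if len(ok):
        return float(uniq[ok[0]])
    return float(np.nextafter(neg[-1], np.inf))


# ---------------------------------------------------------------------------
# the trained predictor

@dataclass
class TrainedPredictor:
    """Fitted scaler + SVM + thresholds, plus provenance metadata."""

    mode: str
    taxon: str
    scaler: FeatureScaler
    svc: SVC
    C: float
    gamma: float
    thresholds: Optional[ThresholdTable] = None
    layout: tuple = ()
    seed: int = 0
    n_shuffles: int = N_SHUFFLES
    fold_backend: str = "builtin"
    provenance: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Signed decision values; larger means more likely methylated."""
        return self.svc.decision_function(apply_scaler(self.scaler, X))


def train(
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    C: float,
    gamma: float,
    taxon: str = "mammal",
    seed: int = 0,
    n_shuffles: int = N_SHUFFLES,
    fold_backend: str = "builtin",
    provenance: Optional[dict] = None,
) -> TrainedPredictor:
    """Fit the scaler + RBF SVM on a labeled feature matrix.

    ``y`` must contain both classes (1 = methylated, 0 = not).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if X.shape[1] != feature_dim(mode):
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns; mode {mode!r} "
            f"expects {feature_dim(mode)}"
        )
    scaler = fit_scaler(X)
    svc = SVC(kernel="rbf", C=C, gamma=gamma, tol=SVC_TOL)
    svc.fit(apply_scaler(scaler, X), y)
    return TrainedPredictor(
        mode=mode,
        taxon=taxon,
        scaler=scaler,
        svc=svc,
        C=float(C),
        gamma=float(gamma),
        layout=feature_layout(mode),
        seed=int(seed),
        n_shuffles=int(n_shuffles),
        fold_backend=fold_backend,
        provenance=dict(provenance or {}),
    )


def calibrate_thresholds(
    predictor: TrainedPredictor,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    targets: Optional[dict] = None,
) -> ThresholdTable:
    """Calibrate stringency thresholds against a set with negatives.

    For each target specificity the threshold is the smallest decision
    value whose empirical specificity on the calibration negatives
    reaches the target; the achieved specificity is reported alongside.
    By default the calibration set is the training data (negatives
    only are used).
    """
    if targets is None:
        targets = DEFAULT_TARGET_SPECIFICITIES[predictor.mode]
    y_cal = np.asarray(y_cal, dtype=int)
    neg = np.asarray(X_cal, dtype=float)[y_cal == 0]
    if len(neg) == 0:
        raise ValueError("calibration set contains no negatives")
    neg_scores = predictor.score(neg)
    entries = {}
    for level, target in targets.items():
        thr = threshold_for_specificity(neg_scores, target)
        achieved = float(np.mean(neg_scores < thr))
        entries[level] = ThresholdEntry(thr, achieved, float(target))
    table = ThresholdTable(entries)
    predictor.thresholds = table
    return table


# ---------------------------------------------------------------------------
# whole-transcript prediction

@dataclass(frozen=True)
class SitePrediction:
    site: CandidateSite
    score: float
    passes: dict  # level -> bool


def predict_sites(
    predictor: TrainedPredictor,
    transcripts: Sequence[Transcript],
    seed: Optional[int] = None,
) -> list[SitePrediction]:
    """Scan and score every DRACH candidate of the given transcripts.

    The transcripts' mode tag must match the predictor's mode.  The
    per-site shuffle seed defaults to the seed the model was trained
    with, so predictions are reproducible from the model file alone.
    """
    if predictor.thresholds is None:
        raise ValueError("predictor has no calibrated thresholds")
    for t in transcripts:
        if t.mode != predictor.mode:
            raise ValueError(
                f"transcript {t.id!r} is tagged mode {t.mode!r} but the "
                f"model is {predictor.mode!r}"
            )
    seed = predictor.seed if seed is None else seed
    out: list[SitePrediction] = []
    tmap = {t.id: t for t in transcripts}
    for t in transcripts:
        sites = scan_drach(t)
        if not sites:
            continue
        X = assemble_matrix(
            sites, tmap, predictor.mode, seed=seed, n_shuffles=predictor.n_shuffles
        )
        scores = predictor.score(X)
        for site, sc in zip(sites, scores):
            passes = {
                lv: bool(sc >= predictor.thresholds.threshold(lv))
                for lv in predictor.thresholds.levels
            }
            out.append(SitePrediction(site, float(sc), passes))
    return out


def predictions_to_frame(predictions: Iterable[SitePrediction]):
    """Tabulate predictions (one row per candidate site)."""
    import pandas as pd

    rows = []
    for p in predictions:
        row = {
            "transcript_id": p.site.transcript_id,
            "pos": p.site.pos,
            "motif": p.site.motif,
            "score": p.score,
        }
        row.update({f"passes_{lv}": v for lv, v in p.passes.items()})
        rows.append(row)
    cols = ["transcript_id", "pos", "motif", "score"] + [
        f"passes_{lv}" for lv in LEVELS
    ]
    return pd.DataFrame(rows, columns=cols if rows else cols)


# ---------------------------------------------------------------------------
# persistence

def save_model(predictor: TrainedPredictor, path: Union[str, Path]) -> None:
    """Persist a predictor as a self-describing archive."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "metadata": {
            "package_version": _PKG_VERSION,
            "mode": predictor.mode,
            "taxon": predictor.taxon,
            "C": predictor.C,
            "gamma": predictor.gamma,
            "layout": list(map(list, predictor.layout)),
            "seed": predictor.seed,
            "n_shuffles": predictor.n_shuffles,
            "fold_backend": predictor.fold_backend,
            "thresholds": (
                predictor.thresholds.to_dict() if predictor.thresholds else None
            ),
            "provenance": predictor.provenance,
        },
        "state": {
            "scaler_mean": predictor.scaler.mean,
            "scaler_sd": predictor.scaler.sd,
            "svc": predictor.svc,
        },
    }
    joblib.dump(payload, path)


def load_model(path: Union[str, Path]) -> TrainedPredictor:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file {path} does not exist")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / not a joblib archive
        raise ModelFormatError(f"{path}: cannot read model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: model format version {payload.get('version')} "
            f"incompatible with reader version {MODEL_VERSION}"
        )
    meta = payload["metadata"]
    state = payload["state"]
    thresholds = (
        ThresholdTable.from_dict(meta["thresholds"]) if meta["thresholds"] else None
    )
    return TrainedPredictor(
        mode=meta["mode"],
        taxon=meta["taxon"],
        scaler=FeatureScaler(
            np.asarray(state["scaler_mean"]), np.asarray(state["scaler_sd"])
        ),
        svc=state["svc"],
        C=meta["C"],
        gamma=meta["gamma"],
        thresholds=thresholds,
        layout=tuple(map(tuple, meta["layout"])),
        seed=meta["seed"],
        n_shuffles=meta["n_shuffles"],
        fold_backend=meta["fold_backend"],
        provenance=meta.get("provenance", {}),
    )
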