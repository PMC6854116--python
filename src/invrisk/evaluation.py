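"""Model validation: 10-fold cross-validation, ROC/AUC, calibration R2.

Cross-validation follows the unstratified random-partition protocol:
refit on 90%, predict the held-out 10%, repeat over all folds and
average the misclassification rate (threshold 0.5). Out-of-fold
predictions are pooled for a single ROC curve, since per-fold ROC is
unstable with ~22 observations per fold at 7% prevalence. Folds whose
training split has a single-class response cannot be refitted and are
skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import FitError, ValidationError
from .glm_core import DesignSpec, fit_logistic

__all__ = ["CvResult", "RocCurve", "kfold_cv", "roc_auc", "calibration_r2"]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and AUC with ties counted one-half.

    AUC is the probability that a randomly chosen positive outranks a
    randomly chosen negative (equivalently, trapezoidal integration of
    the ROC curve over all thresholds).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present to compute AUC")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr,
                    auc=float(roc_auc_score(labels, scores)))


@dataclass(frozen=True)
class CvResult:
    fold_assignments: np.ndarray
    oof_probabilities: np.ndarray
    fold_error_rates: tuple[float, ...]
    error_rate: float
    auc: float
    skipped_folds: tuple[int, ...] = field(default=())


def kfold_cv(
    design: DesignSpec,
    data: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    threshold: float = 0.5,
) -> CvResult:
    """Unstratified k-fold cross-validation of a logistic design."""
    n = len(data)
    if n < k:
        raise ValidationError(f"need at least k={k} observations, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f

    y = data[design.response].to_numpy(dtype=float)
    oof = np.full(n, np.nan)
    errors: list[float] = []
    skipped: list[int] = []
    for f in range(k):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(
                f"fold {f}: training response is single-class; fold skipped",
                stacklevel=2)
            skipped.append(f)
            continue
        try:
            model = fit_logistic(design, data.loc[train])
            p = model.predict(data.loc[test])
        except FitError as exc:
            warnings.warn(f"fold {f}: {exc}; fold skipped", stacklevel=2)
            skipped.append(f)
            continue
        oof[test] = p
        errors.append(float(np.mean((p >= threshold).astype(float) != y[test])))

    if not errors:
        raise FitError("every fold failed to fit")
    scored = ~np.isnan(oof)
    auc = (roc_auc(oof[scored], y[scored].astype(int)).auc
           if len(np.unique(y[scored])) == 2 else np.nan)
    return CvResult(
        fold_assignments=folds,
        oof_probabilities=oof,
        fold_error_rates=tuple(errors),
        error_rate=float(np.mean(errors)),
        auc=float(auc),
        skipped_folds=tuple(skipped),
    )


def calibration_r2(bin_means: Sequence[float], bin_observed: Sequence[float]) -> float:
    """R2 of the least-squares regression of observed on predicted bins."""
    x = np.asarray(bin_means, dtype=float)
    yy = np.asarray(bin_observed, dtype=float)
    if x.size != yy.size:
        raise ValidationError("bin vectors must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 bins")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in predicted bin means")
    res = scipy.stats.linregress(x, yy)
    return float(res.rvalue**2)
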