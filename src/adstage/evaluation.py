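"""Multiclass evaluation: confusion matrices, metric reports, ROC/PR curves,
and cross-validation fold aggregation.

Precision, recall, F1, AUROC and AUPR are macro-averaged one-vs-rest
(micro available via the `average` flag); Cohen's kappa uses the standard
observed-vs-expected agreement formula.  Classes absent from the ground
truth are excluded from the macro curve averages with a logged warning.
Fold aggregation appends an arithmetic-mean row and a sample
standard-deviation row (ddof = 1).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "compute_metrics", "roc_pr_curves", "aggregate_folds"]

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray       # (C, C) ints, rows = true, cols = predicted

    @property
    def normalized(self) -> np.ndarray:
        rs = self.counts.sum(axis=1, keepdims=True).astype(float)
        out = np.divide(self.counts, rs, out=np.zeros_like(self.counts, float),
                        where=rs > 0)
        return out

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n)


def _check_range(arr, c, name):
    arr = np.asarray(arr, dtype=int)
    if arr.size and (arr.min() < 0 or arr.max() >= c):
        raise ValueError(f"{name} entries must lie in 0..{c - 1}")
    return arr


def confusion_matrix(y_true, y_pred, n_classes: int = 4) -> ConfusionMatrix:
    yt = _check_range(y_true, n_classes, "y_true")
    yp = _check_range(y_pred, n_classes, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (yt, yp), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    aupr: float
    kappa: float
    fold_id: int | str = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(y_true, y_pred, probs, n_classes: int = 4,
                    fold_id: int | str = 0,
                    average: str = "macro") -> MetricsReport:
    """Full metric set from hard predictions and predicted probabilities."""
    yt = _check_range(y_true, n_classes, "y_true")
    yp = _check_range(y_pred, n_classes, "y_pred")
    probs = np.asarray(probs, dtype=float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    cm = confusion_matrix(yt, yp, n_classes)
    prec, rec, f1, _ = skm.precision_recall_fscore_support(
        yt, yp, labels=np.arange(n_classes), average=average, zero_division=0)
    kappa = skm.cohen_kappa_score(yt, yp, labels=np.arange(n_classes))

    present = np.unique(yt)
    absent = sorted(set(range(n_classes)) - set(present))
    if absent:
        log.warning("classes %s absent from y_true; excluded from curve "
                    "averages", absent)
    aurocs, auprs = [], []
    for c in present:
        bin_true = (yt == c).astype(int)
        if bin_true.all():
            log.warning("class %d is the only class present; curves undefined", c)
            continue
        aurocs.append(skm.roc_auc_score(bin_true, probs[:, c]))
        auprs.append(skm.average_precision_score(bin_true, probs[:, c]))
    return MetricsReport(accuracy=cm.accuracy, precision=float(prec),
                         recall=float(rec), f1=float(f1),
                         auroc=float(np.mean(aurocs)),
                         aupr=float(np.mean(auprs)), kappa=float(kappa),
                         fold_id=fold_id)


def roc_pr_curves(y_true, probs, n_classes: int = 4) -> dict[int, dict]:
    """One-vs-rest ROC and PR point lists plus trapezoidal areas, per class."""
    yt = _check_range(y_true, n_classes, "y_true")
    probs = np.asarray(probs, dtype=float)
    out: dict[int, dict] = {}
    for c in range(n_classes):
        bin_true = (yt == c).astype(int)
        if bin_true.sum() in (0, len(bin_true)):
            log.warning("one-vs-rest curve for class %d undefined; skipped", c)
            continue
        fpr, tpr, roc_thr = skm.roc_curve(bin_true, probs[:, c])
        prec, rec, pr_thr = skm.precision_recall_curve(bin_true, probs[:, c])
        out[c] = {
            "fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr,
            "precision": prec, "recall": rec, "pr_thresholds": pr_thr,
            "auroc": float(skm.auc(fpr, tpr)),
            "aupr": float(skm.average_precision_score(bin_true, probs[:, c])),
        }
    return out


def aggregate_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-fold rows plus mean and sample-std (ddof=1) summary rows."""
    if not reports:
        raise ValueError("need at least one fold report")
    rows = [r.to_dict() for r in reports]
    df = pd.DataFrame(rows).set_index("fold_id")
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=1) if len(df) > 1 else df.iloc[0] * 0.0
    df.loc["mean"] = mean
    df.loc["std"] = std
    return df
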