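"""Progression-aware error analysis.

Because the four stages are ordered, errors differ in clinical severity:
an adjacent-stage confusion (Delta = |y - y_hat| = 1) is far more plausible
than a maximal-distance one (Delta = 3, e.g. calling a moderate-dementia
slice non-demented).  This module decomposes predictions into

* the Delta histogram (counts and percentages, on two bases: over all
  predictions and over errors only, both labeled);
* a distance-aware confusion matrix pairing each cell count with |i - j|;
* the directional split into underestimation (y_hat < y, predicting a less
  advanced stage) and overestimation (y_hat > y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ConfusionMatrix

__all__ = ["OrdinalErrorReport", "ordinal_errors", "distance_matrix",
           "directionality_summary"]


@dataclass
class OrdinalErrorReport:
    n: int
    n_classes: int
    delta_counts: np.ndarray       # length C, index = Delta
    delta_percent: np.ndarray      # base: all predictions; sums to 100
    delta_percent_errors_only: np.ndarray  # base: erroneous predictions
    mean_absolute_error: float
    under_count: int
    exact_count: int
    over_count: int
    max_delta_present: int

    @property
    def has_implausible_errors(self) -> bool:
        """True when any maximal-distance (Delta = C-1) error occurred."""
        return self.max_delta_present == self.n_classes - 1

    def to_dict(self) -> dict:
        return {
            "n": self.n, "n_classes": self.n_classes,
            "delta_counts": self.delta_counts.tolist(),
            "delta_percent": self.delta_percent.tolist(),
            "delta_percent_errors_only": self.delta_percent_errors_only.tolist(),
            "mean_absolute_error": self.mean_absolute_error,
            "under_count": self.under_count, "exact_count": self.exact_count,
            "over_count": self.over_count,
            "max_delta_present": self.max_delta_present,
            "has_implausible_errors": self.has_implausible_errors,
        }


def ordinal_errors(y_true, y_pred, n_classes: int = 4) -> OrdinalErrorReport:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0:
        raise ValueError("need at least one prediction")
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if yt.min() < 0 or yt.max() >= n_classes or yp.min() < 0 or yp.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    signed = yp - yt                       # >0 = overestimation
    delta = np.abs(signed)
    counts = np.bincount(delta, minlength=n_classes)
    n = yt.size
    n_err = int((delta > 0).sum())
    pct = counts / n * 100.0
    pct_err = np.zeros(n_classes)
    if n_err:
        pct_err[1:] = counts[1:] / n_err * 100.0
    return OrdinalErrorReport(
        n=n, n_classes=n_classes, delta_counts=counts, delta_percent=pct,
        delta_percent_errors_only=pct_err,
        mean_absolute_error=float(delta.mean()),
        under_count=int((signed < 0).sum()),
        exact_count=int((signed == 0).sum()),
        over_count=int((signed > 0).sum()),
        max_delta_present=int(delta.max()),
    )


def distance_matrix(cm: ConfusionMatrix) -> dict:
    """Annotate each confusion cell with its ordinal distance |i - j|.

    Returns the per-cell (count, distance) arrays plus the count mass at
    each distance, which equals the Delta histogram of the raw predictions
    that produced the confusion matrix.
    """
    c = cm.counts.shape[0]
    i, j = np.indices((c, c))
    dist = np.abs(i - j)
    mass = np.zeros(c, dtype=int)
    np.add.at(mass, dist.ravel(), cm.counts.ravel())
    return {"counts": cm.counts.copy(), "distance": dist,
            "distance_mass": mass}


def directionality_summary(report: OrdinalErrorReport) -> dict:
    """Under/exact/over proportions and the conservative-bias flag.

    The flag is True when underestimation errors outnumber overestimation
    errors — the clinically "conservative" pattern in which the model errs
    toward the less advanced stage.
    """
    n = report.n
    return {
        "under_proportion": report.under_count / n,
        "exact_proportion": report.exact_count / n,
        "over_proportion": report.over_count / n,
        "conservative_bias": report.under_count > report.over_count,
    }
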