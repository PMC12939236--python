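"""Composite training objective for ordinal staging.

Three terms:

* cross-entropy  L_CE  — standard multiclass classification loss;
* ordinal expectation loss  L_ord = mean (s_hat - y)^2  with
  s_hat = sum_c c * p_c, the probability-weighted mean class index, which
  penalizes confident predictions far from the true stage quadratically in
  the stage distance (a point mass on class k costs (k - y)^2);
* flip-consistency loss  L_cons = mean || p - p_tilde ||^2  between the
  predicted distributions of an image and its horizontally flipped view.

Total:  L = L_CE + lambda1 * L_ord + lambda2 * L_cons, with default weights
lambda1 = 0.3 and lambda2 = 0.2.  All batch reductions are arithmetic means.

Every loss accepts either plain numpy arrays (returning a float) or autograd
Tensors (returning a Tensor through which gradients flow; the consistency
term back-propagates into both views).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossWeights", "LossBreakdown", "cross_entropy", "ordinal_loss",
           "consistency_loss", "total_loss", "composite_loss"]


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 0.3   # ordinal term
    lambda2: float = 0.2   # consistency term

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    ce: float
    ordinal: float
    consistency: float
    total: float


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _check_labels(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("labels must be a 1D array")
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    return y.astype(int)


def _maybe_float(out: Tensor, was_tensor: bool):
    return out if was_tensor else float(out.data)


def cross_entropy(logits, y, class_weights: np.ndarray | None = None):
    """Mean negative log softmax probability of the true class."""
    was_tensor = isinstance(logits, Tensor)
    lt = _as_tensor(logits)
    n, c = lt.shape
    y = _check_labels(y, c)
    onehot = np.zeros((n, c))
    onehot[np.arange(n), y] = 1.0
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=float)[y]
        onehot *= (w / w.mean())[:, None]
    out = -(lt.log_softmax(axis=-1) * Tensor(onehot)).sum() * (1.0 / n)
    return _maybe_float(out, was_tensor)


def ordinal_loss(logits, y):
    """Mean squared distance between the expected stage index and the truth."""
    was_tensor = isinstance(logits, Tensor)
    lt = _as_tensor(logits)
    n, c = lt.shape
    y = _check_labels(y, c)
    idx = Tensor(np.arange(c, dtype=float))
    s_hat = (lt.softmax(axis=-1) * idx).sum(axis=-1)
    out = ((s_hat - Tensor(y.astype(float))) ** 2).mean()
    return _maybe_float(out, was_tensor)


def consistency_loss(p, p_tilde, atol: float = 1e-5):
    """Mean squared Euclidean distance between paired probability rows."""
    was_tensor = isinstance(p, Tensor) or isinstance(p_tilde, Tensor)
    pt, qt = _as_tensor(p), _as_tensor(p_tilde)
    if pt.shape != qt.shape:
        raise ValueError("probability batches must have matching shapes")
    for name, t in (("p", pt), ("p_tilde", qt)):
        rows = t.data.sum(axis=-1)
        if np.abs(rows - 1.0).max() > atol:
            raise ValueError(f"rows of {name} must sum to 1")
    out = (((pt - qt) ** 2).sum(axis=-1)).mean()
    return _maybe_float(out, was_tensor)


def composite_loss(logits: Tensor, logits_tilde: Tensor, y,
                   weights: LossWeights = LossWeights()
                   ) -> tuple[Tensor, LossBreakdown]:
    """Differentiable total loss plus its per-term breakdown.

    CE and the ordinal term use the original view's logits only; the
    consistency term couples the softmax outputs of both views.
    """
    if logits.shape != logits_tilde.shape:
        raise ValueError("paired batches must have the same shape")
    ce = cross_entropy(logits, y)
    orl = ordinal_loss(logits, y)
    cons = consistency_loss(logits.softmax(axis=-1),
                            logits_tilde.softmax(axis=-1))
    total = ce + weights.lambda1 * orl + weights.lambda2 * cons
    bd = LossBreakdown(ce=float(ce.data), ordinal=float(orl.data),
                       consistency=float(cons.data), total=float(total.data))
    return total, bd


def total_loss(logits, logits_tilde, y,
               weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Numpy-facing wrapper returning the breakdown of the composite loss."""
    _, bd = composite_loss(_as_tensor(logits), _as_tensor(logits_tilde), y,
                           weights)
    return bd
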