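"""Leakage-free k-fold training.

The protocol: original slices are partitioned into K stratified folds
*before* any augmentation, so no transformed copy of a validation slice can
reach the training set; augmented records always inherit their parent's
fold.  Training applies stochastic rotation / horizontal-flip / random
resized crop augmentation and optimizes the composite objective (CE +
ordinal + flip-consistency) with AdamW; the consistency view is the
horizontal flip of the training input.  Validation applies resizing and
normalization only.  Early stopping monitors validation accuracy and the
returned weights are those of the best-validation epoch.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .datagen import ImageRecord, LabeledDataset
from .evaluation import MetricsReport, aggregate_folds, compute_metrics
from .model import CnnBaseline, ModelConfig, build_model
from .nn import AdamW, Tensor
from .objectives import LossWeights, composite_loss

__all__ = ["FoldSplit", "AugmentParams", "TrainConfig", "TrainHistory",
           "Normalizer", "make_folds", "augment", "hflip", "train_fold",
           "predict", "run_cross_validation", "CVResult"]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# fold assignment
# --------------------------------------------------------------------------

@dataclass
class FoldSplit:
    K: int
    assignments: dict[str, int]      # original record id -> fold index
    group_by_subject: bool = False

    def fold_of(self, record: ImageRecord) -> int:
        """Fold of a record; augmented records inherit their parent's fold."""
        rid = record.id if record.provenance == "original" else record.parent_id
        return self.assignments[rid]

    def val_ids(self, k: int) -> set[str]:
        return {i for i, f in self.assignments.items() if f == k}

    def train_ids(self, k: int) -> set[str]:
        return {i for i, f in self.assignments.items() if f != k}


def make_folds(ds: LabeledDataset, K: int = 5, seed: int = 0,
               group_by_subject: bool = False) -> FoldSplit:
    """Stratified random partition of the original records into K folds."""
    if K < 2:
        raise ValueError("K must be >= 2")
    originals = ds.originals()
    if len(originals) != len(ds.records):
        raise ValueError("fold splitting must happen before augmentation: "
                         "dataset contains augmented records")
    y = np.array([r.label for r in originals])
    if np.bincount(y, minlength=4).min() < K:
        raise ValueError(f"every class needs at least K={K} records for "
                         "stratified splitting")
    ids = np.array([r.id for r in originals])
    assignments: dict[str, int] = {}
    if group_by_subject:
        groups = np.array([r.subject_id or r.id for r in originals])
        splitter = StratifiedGroupKFold(n_splits=K, shuffle=True,
                                        random_state=seed)
        folds = splitter.split(ids, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        folds = splitter.split(ids, y)
    for k, (_, val_idx) in enumerate(folds):
        for i in val_idx:
            assignments[ids[i]] = k
    return FoldSplit(K=K, assignments=assignments,
                     group_by_subject=group_by_subject)


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Mild, anatomy-preserving training augmentation."""

    rotation_deg: float = 10.0          # uniform in [-deg, +deg]
    flip_prob: float = 0.5
    crop_scale: tuple[float, float] = (0.8, 1.0)
    enabled: bool = True


def hflip(pixels: np.ndarray) -> np.ndarray:
    return pixels[:, ::-1].copy()


def augment(record: ImageRecord, rng: np.random.Generator,
            params: AugmentParams = AugmentParams(),
            suffix: str = "aug") -> ImageRecord:
    """Stochastic rotation + horizontal flip + random resized crop.

    With rotation_deg=0, flip_prob=0 and crop_scale=(1,1) this is the
    identity transform.  The result carries provenance 'augmented' and a
    parent link for leakage accounting.
    """
    img = record.pixels
    h, w = img.shape
    if params.rotation_deg > 0:
        angle = rng.uniform(-params.rotation_deg, params.rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="constant", cval=0.0)
    if rng.random() < params.flip_prob:
        img = hflip(img)
    lo, hi = params.crop_scale
    scale = rng.uniform(lo, hi)
    if scale < 1.0:
        ch, cw = max(8, int(round(h * scale))), max(8, int(round(w * scale)))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        img = resize(img[top:top + ch, left:left + cw], (h, w), order=1,
                     mode="edge", anti_aliasing=False)
    img = np.clip(img, 0.0, 1.0)
    return ImageRecord(id=f"{record.id}_{suffix}", pixels=img,
                       label=record.label, subject_id=record.subject_id,
                       provenance="augmented", parent_id=record.id)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    patience: int = 10
    seed: int = 0
    augmentation: AugmentParams = AugmentParams()
    mixed_precision: bool = False   # reserved flag; CPU path is full precision

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_dict(self) -> dict:
        return {"train_loss": self.train_loss, "train_acc": self.train_acc,
                "val_loss": self.val_loss, "val_acc": self.val_acc,
                "best_epoch": self.best_epoch,
                "stopped_early": self.stopped_early}


@dataclass(frozen=True)
class Normalizer:
    """Deterministic resize-to-model-input + z-score normalization."""

    mean: float
    sd: float
    input_size: int

    @classmethod
    def fit(cls, records: list[ImageRecord], input_size: int) -> "Normalizer":
        vals = np.concatenate([r.pixels.ravel() for r in records])
        return cls(mean=float(vals.mean()), sd=float(max(vals.std(), 1e-8)),
                   input_size=input_size)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        if pixels.shape != (self.input_size, self.input_size):
            pixels = resize(pixels, (self.input_size, self.input_size),
                            order=1, mode="edge", anti_aliasing=False)
        return (pixels - self.mean) / self.sd


def _batch_array(images: list[np.ndarray]) -> np.ndarray:
    return np.stack(images)[:, None, :, :]


def check_leakage(train_records: list[ImageRecord],
                  val_records: list[ImageRecord]) -> None:
    """Hard error when train/val share an id or an augmentation lineage."""
    def lineage(r: ImageRecord) -> str:
        return r.id if r.provenance == "original" else r.parent_id

    train_lin = {lineage(r) for r in train_records}
    val_lin = {lineage(r) for r in val_records}
    shared = train_lin & val_lin
    if shared:
        raise ValueError(f"train/validation leakage detected: shared lineages "
                         f"{sorted(shared)[:5]}{'...' if len(shared) > 5 else ''}")


def predict(model, records: list[ImageRecord], normalizer: Normalizer,
            batch_size: int = 32, return_tokens: bool = False):
    """Deterministic eval-mode predictions (probs, preds[, token norms])."""
    model.eval()
    probs, norms = [], []
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        x = _batch_array([normalizer(r.pixels) for r in chunk])
        out = model.forward(x)
        probs.append(out.probabilities)
        if return_tokens and out.final_tokens.size:
            norms.append(np.sqrt((out.final_tokens ** 2).sum(axis=2)))
    probs = np.concatenate(probs)
    preds = probs.argmax(axis=1)
    if return_tokens:
        return probs, preds, (np.concatenate(norms) if norms else None)
    return probs, preds


def train_fold(model_cfg: ModelConfig, train_records: list[ImageRecord],
               val_records: list[ImageRecord], cfg: TrainConfig,
               weights: LossWeights = LossWeights(),
               ablation: bool = False):
    """Train one model on one fold; returns (model, normalizer, history)."""
    check_leakage(train_records, val_records)
    rng = np.random.default_rng(cfg.seed)
    model = build_model(model_cfg, ablation=ablation)
    normalizer = Normalizer.fit(train_records, model_cfg.input_size)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)

    history = TrainHistory()
    best_acc, best_state, since_best = -np.inf, None, 0
    n = len(train_records)
    use_consistency = weights.lambda2 > 0

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            batch = [train_records[j] for j in order[i:i + cfg.batch_size]]
            if cfg.augmentation.enabled:
                batch_imgs = [augment(r, rng, cfg.augmentation).pixels
                              for r in batch]
            else:
                batch_imgs = [r.pixels for r in batch]
            y = np.array([r.label for r in batch])
            x = _batch_array([normalizer(p) for p in batch_imgs])
            logits, _, _ = model.forward_tensors(x)
            if use_consistency:
                x_t = _batch_array([normalizer(hflip(p)) for p in batch_imgs])
                logits_t, _, _ = model.forward_tensors(x_t)
            else:
                logits_t = logits
            total, bd = composite_loss(logits, logits_t, y, weights)
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_loss += bd.total * len(batch)
            ep_correct += int((logits.data.argmax(axis=1) == y).sum())
        history.train_loss.append(ep_loss / n)
        history.train_acc.append(ep_correct / n)

        probs, preds = predict(model, val_records, normalizer,
                               batch_size=max(cfg.batch_size, 32))
        yv = np.array([r.label for r in val_records])
        val_acc = float((preds == yv).mean())
        onehot_ll = -np.log(np.clip(probs[np.arange(len(yv)), yv], 1e-12, 1.0))
        history.val_loss.append(float(onehot_ll.mean()))
        history.val_acc.append(val_acc)
        log.info("epoch %d: train_loss=%.4f train_acc=%.4f val_acc=%.4f",
                 epoch, history.train_loss[-1], history.train_acc[-1], val_acc)

        if val_acc > best_acc:
            best_acc, since_best = val_acc, 0
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
        else:
            since_best += 1
            if since_best > cfg.patience:
                history.stopped_early = True
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, normalizer, history


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    split: FoldSplit
    fold_reports: list[MetricsReport]
    aggregate: pd.DataFrame
    predictions: pd.DataFrame        # id, fold, true, pred, p0..p3
    token_norms: pd.DataFrame | None  # id, fold, true, pred, norm00..norm15
    histories: list[TrainHistory]
    models: list
    normalizers: list[Normalizer]


def run_cross_validation(ds: LabeledDataset, model_cfg: ModelConfig,
                         cfg: TrainConfig,
                         weights: LossWeights = LossWeights(),
                         K: int = 5, group_by_subject: bool = False,
                         ablation: bool = False,
                         keep_models: bool = True) -> CVResult:
    """Train K independent seeded models and aggregate their fold metrics."""
    split = make_folds(ds, K=K, seed=cfg.seed,
                       group_by_subject=group_by_subject)
    by_id = {r.id: r for r in ds.originals()}
    reports, histories, models, normalizers = [], [], [], []
    pred_rows, norm_rows = [], []
    n_classes = model_cfg.n_classes
    for k in range(K):
        train_recs = [by_id[i] for i in sorted(split.train_ids(k))]
        val_recs = [by_id[i] for i in sorted(split.val_ids(k))]
        fold_cfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                               learning_rate=cfg.learning_rate,
                               weight_decay=cfg.weight_decay,
                               patience=cfg.patience, seed=cfg.seed + k,
                               augmentation=cfg.augmentation,
                               mixed_precision=cfg.mixed_precision)
        fold_model_cfg = ModelConfig.from_dict(
            {**model_cfg.to_dict(), "seed": model_cfg.seed + k})
        model, normalizer, hist = train_fold(fold_model_cfg, train_recs,
                                             val_recs, fold_cfg, weights,
                                             ablation=ablation)
        want_tokens = not ablation
        out = predict(model, val_recs, normalizer, return_tokens=want_tokens)
        probs, preds, norms = out if want_tokens else (*out, None)
        y = np.array([r.label for r in val_recs])
        reports.append(compute_metrics(y, preds, probs, n_classes, fold_id=k))
        for j, r in enumerate(val_recs):
            pred_rows.append({"id": r.id, "fold": k, "true": r.label,
                              "pred": int(preds[j]),
                              **{f"p{c}": probs[j, c] for c in range(n_classes)}})
            if norms is not None:
                norm_rows.append({"id": r.id, "fold": k, "true": r.label,
                                  "pred": int(preds[j]),
                                  **{f"norm{t:02d}": norms[j, t]
                                     for t in range(norms.shape[1])}})
        histories.append(hist)
        normalizers.append(normalizer)
        if keep_models:
            models.append(model)
    return CVResult(split=split, fold_reports=reports,
                    aggregate=aggregate_folds(reports),
                    predictions=pd.DataFrame(pred_rows),
                    token_norms=pd.DataFrame(norm_rows) if norm_rows else None,
                    histories=histories, models=models,
                    normalizers=normalizers)
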