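"""Token-level interpretability.

The importance of spatial token i is the L2 norm of its final transformer
embedding (row i of T2).  The 16 norms are reshaped row-major to the 4x4
grid and min-max normalized to [0,1] per slice (all-equal norms map to all
ones by convention).  On top of the maps this module provides: overlays on
the source slice, class-wise mean maps, rank-stability profiles, top-k
concentration scores, and the stage-vs-concentration Spearman trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.stats import spearmanr

__all__ = ["ImportanceMap", "ConcentrationProfile", "token_importance",
           "overlay", "classwise_mean_maps", "rank_stability",
           "concentration_score", "stage_concentration_trend"]


@dataclass
class ImportanceMap:
    raw_norms: np.ndarray          # 16 non-negative reals, row-major
    grid: np.ndarray               # 4x4 in [0,1], max = 1
    slice_id: str = ""
    predicted_stage: int | None = None
    true_stage: int | None = None


@dataclass
class ConcentrationProfile:
    k: int
    per_slice_scores: np.ndarray
    per_stage_mean: np.ndarray     # length 4; nan for absent stages
    stage_correlation: float       # Spearman rho of (stage, score)


def token_importance(t2: np.ndarray, slice_id: str = "",
                     predicted_stage: int | None = None,
                     true_stage: int | None = None) -> ImportanceMap:
    """Per-token L2 norms of T2 (16 x D), as a normalized 4x4 map."""
    t2 = np.asarray(t2, dtype=float)
    if t2.ndim != 2 or t2.shape[0] != 16:
        raise ValueError("T2 must be a 16 x D matrix")
    if not np.isfinite(t2).all():
        raise ValueError("non-finite token embeddings")
    norms = np.sqrt((t2 ** 2).sum(axis=1))
    lo, hi = norms.min(), norms.max()
    if hi - lo < 1e-12:
        grid = np.ones(16)         # all-equal convention
    else:
        grid = (norms - lo) / (hi - lo)
    return ImportanceMap(raw_norms=norms, grid=grid.reshape(4, 4),
                         slice_id=slice_id, predicted_stage=predicted_stage,
                         true_stage=true_stage)


def overlay(imap: ImportanceMap, image: np.ndarray,
            path: str | Path | None = None, alpha: float = 0.45) -> np.ndarray:
    """Bilinearly upsample the 4x4 grid, warm-colormap it, and alpha-blend
    it over the grayscale slice.  Returns the HxWx3 uint8 render; writes a
    PNG when `path` is given."""
    import matplotlib
    from skimage.transform import resize

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale slice")
    h, w = image.shape
    heat = resize(imap.grid, (h, w), order=1, mode="edge",
                  anti_aliasing=False)
    colored = matplotlib.colormaps["hot"](heat)[..., :3]
    base = np.stack([image] * 3, axis=-1)
    blend = (1 - alpha) * base + alpha * colored
    out = np.clip(np.round(blend * 255), 0, 255).astype(np.uint8)
    if path is not None:
        Image.fromarray(out).save(Path(path))
    return out


def classwise_mean_maps(maps: list[ImportanceMap],
                        n_classes: int = 4) -> dict[int, np.ndarray]:
    """Mean normalized grid over all slices of each true stage."""
    import logging
    out: dict[int, np.ndarray] = {}
    for stage in range(n_classes):
        grids = [m.grid for m in maps if m.true_stage == stage]
        if not grids:
            logging.getLogger(__name__).warning(
                "no slices with true stage %d; mean map omitted", stage)
            continue
        out[stage] = np.mean(grids, axis=0)
    return out


def rank_stability(maps: list[ImportanceMap]) -> dict[str, np.ndarray]:
    """Mean and std of normalized importance per global token rank.

    Tokens are ordered by their mean normalized importance across slices
    (global relevance); per-rank means are non-increasing by construction.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    flat = np.stack([m.grid.ravel() for m in maps])    # (n_slices, 16)
    order = np.argsort(-flat.mean(axis=0), kind="stable")
    ranked = flat[:, order]
    return {"token_order": order, "rank_mean": ranked.mean(axis=0),
            "rank_std": ranked.std(axis=0)}


def concentration_score(imap: ImportanceMap, k: int = 4) -> float:
    """Fraction of total raw-norm mass carried by the k largest tokens."""
    if not 1 <= k <= 16:
        raise ValueError("k must be in 1..16")
    total = imap.raw_norms.sum()
    if total <= 0:
        raise ValueError("concentration undefined: total token norm is zero")
    top = np.sort(imap.raw_norms)[::-1][:k].sum()
    return float(top / total)


def stage_concentration_trend(maps: list[ImportanceMap], k: int = 4,
                              n_classes: int = 4) -> ConcentrationProfile:
    """Per-stage mean concentration and the Spearman stage-score correlation."""
    stages = np.array([m.true_stage for m in maps])
    if len(np.unique(stages)) < 2:
        raise ValueError("need at least two distinct stages")
    scores = np.array([concentration_score(m, k) for m in maps])
    if np.ptp(scores) < 1e-15:
        raise ValueError("correlation undefined: concentration scores are constant")
    per_stage = np.full(n_classes, np.nan)
    for s in range(n_classes):
        sel = stages == s
        if sel.any():
            per_stage[s] = scores[sel].mean()
    rho = spearmanr(stages, scores).statistic
    return ConcentrationProfile(k=k, per_slice_scores=scores,
                                per_stage_mean=per_stage,
                                stage_correlation=float(rho))
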