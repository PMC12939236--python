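"""Synthetic 4-stage brain phantoms and class-folder image I/O.

The phantom emulates the essential structure of skull-stripped 2D brain MRI
slices used for dementia staging: a bright elliptical "brain" on a dark
background, a dark central "ventricle" whose area grows strictly with the
ordinal stage (ventricular enlargement), and a bright outer "cortical band"
whose thickness shrinks strictly with stage (cortical thinning).  Optionally
the stage-discriminative geometry can instead be confined to a known
quadrant: a dark "atrophy" patch there grows and darkens with stage while
the central anatomy stays fixed, giving interpretability analyses a
ground-truth discriminative region.

Stages are ordered 0 (non-demented) < 1 (very mild) < 2 (mild) < 3 (moderate
dementia).  Default class proportions mirror the 12800:11200:9856:6528 mix of
the public slice dataset this generator stands in for, scaled by 1/64 to
(200, 175, 154, 102).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["DEFAULT_CLASS_NAMES", "DEFAULT_CLASS_COUNTS", "PhantomParams",
           "ImageRecord", "LabeledDataset", "generate_phantom",
           "generate_dataset", "save_image_folder", "load_image_folder"]

log = logging.getLogger(__name__)

DEFAULT_CLASS_NAMES = ("NonDemented", "VeryMildDemented", "MildDemented",
                       "ModerateDemented")
# 1/64 of the source dataset's 12800 : 11200 : 9856 : 6528 slice counts
DEFAULT_CLASS_COUNTS = (200, 175, 154, 102)

_QUADRANTS = ("center", "upper_left", "upper_right", "lower_left", "lower_right")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and sampling parameters of the phantom generator.

    Lengths are in pixels at the given image_size; defaults are sized for
    224-pixel slices.  `fast_profile()` returns a 64-pixel variant for
    CPU-speed experiments and tests.
    """

    image_size: int = 224
    n_classes: int = 4
    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    ventricle_base_radius: float = 14.0
    ventricle_stage_gain: float = 7.0
    cortical_base_thickness: float = 18.0
    cortical_stage_loss: float = 4.0
    noise_sd: float = 0.05
    discriminative_quadrant: str = "center"
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_classes != 4:
            raise ValueError("the staging problem is fixed at 4 ordered classes")
        if len(self.class_counts) != 4 or any(c <= 0 for c in self.class_counts):
            raise ValueError("class_counts must be 4 positive integers")
        for name in ("ventricle_base_radius", "ventricle_stage_gain",
                     "cortical_base_thickness", "cortical_stage_loss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.discriminative_quadrant not in _QUADRANTS:
            raise ValueError(f"discriminative_quadrant must be one of {_QUADRANTS}")
        # ventricle at the worst stage must stay inside the brain ellipse
        max_r = self.ventricle_base_radius + 3 * self.ventricle_stage_gain
        if max_r >= 0.30 * self.image_size:
            raise ValueError("stage-3 ventricle would overflow the brain ellipse")
        if self.cortical_base_thickness - 3 * self.cortical_stage_loss <= 0:
            raise ValueError("stage-3 cortical band thickness must stay positive")

    @classmethod
    def fast_profile(cls, **overrides) -> "PhantomParams":
        """64-pixel profile with proportionally scaled geometry."""
        base = cls(image_size=64, ventricle_base_radius=4.0,
                   ventricle_stage_gain=2.0, cortical_base_thickness=5.0,
                   cortical_stage_loss=1.2)
        return replace(base, **overrides) if overrides else base


@dataclass
class ImageRecord:
    """One 2D slice: [0,1] pixels, ordinal stage label, provenance."""

    id: str
    pixels: np.ndarray
    label: int
    subject_id: str | None = None
    provenance: str = "original"
    parent_id: str | None = None

    def __post_init__(self):
        if not 0 <= self.label <= 3:
            raise ValueError("label must be in 0..3")
        if self.provenance not in ("original", "augmented"):
            raise ValueError("provenance must be 'original' or 'augmented'")
        if self.provenance == "augmented" and self.parent_id is None:
            raise ValueError("augmented records require a parent_id")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixels must lie in [0, 1]")


@dataclass
class LabeledDataset:
    records: list[ImageRecord]
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")
        known = set(ids)
        for r in self.records:
            if r.parent_id is not None and r.parent_id not in known:
                raise ValueError(f"augmented record {r.id} has unknown parent")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def label_histogram(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))

    def originals(self) -> list[ImageRecord]:
        return [r for r in self.records if r.provenance == "original"]

    def subset(self, ids) -> "LabeledDataset":
        keep = set(ids)
        return LabeledDataset([r for r in self.records if r.id in keep],
                              self.class_names)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _coordinate_grid(size: int):
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return yy - c, xx - c


def _quadrant_center(quadrant: str, size: int) -> tuple[float, float]:
    off = 0.18 * size
    return {
        "upper_left": (-off, -off), "upper_right": (-off, off),
        "lower_left": (off, -off), "lower_right": (off, off),
    }[quadrant]


def generate_phantom(params: PhantomParams, stage: int,
                     rng: np.random.Generator | int | None = None,
                     record_id: str | None = None,
                     subject_id: str | None = None) -> ImageRecord:
    """Render one phantom slice at the given ordinal stage.

    Deterministic given (params, stage, rng state).  With noise_sd = 0 and a
    "center" discriminative quadrant the image is left-right symmetric.

    discriminative_quadrant = "center": the ventricle enlarges and the
    cortical band thins with stage.  Any other value holds the central
    anatomy at its stage-0 baseline and confines the stage signal to an
    atrophy patch in that quadrant (known ground-truth region).
    """
    if not isinstance(stage, (int, np.integer)) or not 0 <= stage <= 3:
        raise ValueError("stage must be an integer in 0..3")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    size = params.image_size
    yy, xx = _coordinate_grid(size)
    # brain fills most of the frame, as in centered skull-stripped slices
    a, b = 0.46 * size, 0.48 * size          # brain semi-axes (x, y)
    brain = (xx / a) ** 2 + (yy / b) ** 2
    img = np.zeros((size, size))
    img[brain <= 1.0] = 0.55                 # parenchyma

    central = params.discriminative_quadrant == "center"
    geom_stage = stage if central else 0   # quadrant mode: fixed central anatomy

    # bright cortical band: outer shell of the brain ellipse, thinning with stage
    thick = params.cortical_base_thickness - params.cortical_stage_loss * geom_stage
    inner = 1.0 - thick / min(a, b)
    band = (brain <= 1.0) & (brain >= inner ** 2)
    img[band] = 0.9

    # dark central ventricle, enlarging with stage
    r = params.ventricle_base_radius + params.ventricle_stage_gain * geom_stage
    vent = (xx / (0.8 * r)) ** 2 + (yy / r) ** 2 <= 1.0
    img[vent] = 0.08

    # quadrant mode: the stage signal is an atrophy patch that grows and
    # darkens with stage inside the chosen quadrant
    if not central:
        cy, cx = _quadrant_center(params.discriminative_quadrant, size)
        pr = 0.06 * size + 0.08 * size * stage / 3.0
        patch = ((xx - cx) ** 2 + (yy - cy) ** 2 <= pr ** 2) & (brain <= 1.0)
        img[patch] = np.maximum(0.08, img[patch] - 0.2 * (1 + stage))

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    rid = record_id or f"phantom_stage{stage}"
    return ImageRecord(id=rid, pixels=img, label=int(stage),
                       subject_id=subject_id or rid)


def generate_dataset(params: PhantomParams) -> LabeledDataset:
    """Seeded dataset with exactly class_counts[s] phantoms per stage."""
    rng = np.random.default_rng(params.seed)
    records = []
    idx = 0
    for stage, count in enumerate(params.class_counts):
        for _ in range(count):
            rid = f"ph{idx:05d}"
            records.append(generate_phantom(params, stage, rng, record_id=rid,
                                            subject_id=f"subj{idx:05d}"))
            idx += 1
    return LabeledDataset(records)


# --------------------------------------------------------------------------
# image-folder I/O (class-per-subdirectory, 8-bit PNG)
# --------------------------------------------------------------------------

def save_image_folder(ds: LabeledDataset, path: str | Path) -> None:
    path = Path(path)
    for name in ds.class_names:
        (path / name).mkdir(parents=True, exist_ok=True)
    for r in ds.records:
        arr = np.round(r.pixels * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path / ds.class_names[r.label]
                                            / f"{r.id}.png")


def load_image_folder(path: str | Path,
                      class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
                      ) -> LabeledDataset:
    """Read a class-per-subdirectory folder of PNG/JPEG slices.

    Labels come from the subdirectory; pixels are rescaled to [0,1] and kept
    single-channel.  Unreadable files are skipped with a logged summary.
    """
    path = Path(path)
    missing = [n for n in class_names if not (path / n).is_dir()]
    if missing:
        raise FileNotFoundError(
            f"missing class directories under {path}: {missing}")
    records, skipped = [], 0
    for label, name in enumerate(class_names):
        for f in sorted((path / name).iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                img = Image.open(f).convert("L")
            except Exception:
                skipped += 1
                log.warning("skipping unreadable image %s", f)
                continue
            arr = np.asarray(img, dtype=float) / 255.0
            records.append(ImageRecord(id=f.stem, pixels=arr, label=label,
                                       subject_id=f.stem))
    if skipped:
        log.warning("skipped %d unreadable files under %s", skipped, path)
    return LabeledDataset(records, class_names)
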