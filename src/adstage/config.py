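"""Run configuration: a YAML-round-trippable composite of the phantom,
model, training and loss settings plus evaluation options."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .datagen import PhantomParams
from .model import ModelConfig
from .objectives import LossWeights
from .training import AugmentParams, TrainConfig

__all__ = ["RunConfig"]


def _build(cls, d: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{name}' section: {sorted(unknown)}")
    return cls(**d)


@dataclass
class RunConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    folds: int = 5
    group_by_subject: bool = False
    ablation: bool = False
    seed: int = 0
    out_dir: str = "runs/run0"

    def to_dict(self) -> dict:
        def unlist(x):
            if isinstance(x, dict):
                return {k: unlist(v) for k, v in x.items()}
            if isinstance(x, tuple):
                return [unlist(v) for v in x]
            return x

        d = dataclasses.asdict(self)
        d["model"] = self.model.to_dict()
        return unlist(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        top = {f.name for f in fields(cls)}
        unknown = set(d) - top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        if "phantom" in d:
            p = dict(d["phantom"])
            if "class_counts" in p:
                p["class_counts"] = tuple(p["class_counts"])
            d["phantom"] = _build(PhantomParams, p, "phantom")
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        if "train" in d:
            t = dict(d["train"])
            if "augmentation" in t and isinstance(t["augmentation"], dict):
                a = dict(t["augmentation"])
                if "crop_scale" in a:
                    a["crop_scale"] = tuple(a["crop_scale"])
                t["augmentation"] = _build(AugmentParams, a, "augmentation")
            d["train"] = _build(TrainConfig, t, "train")
        if "loss" in d:
            d["loss"] = _build(LossWeights, dict(d["loss"]), "loss")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
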