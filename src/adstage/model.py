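"""Hybrid CNN-transformer network for 4-stage ordinal staging.

Architecture: a convolutional backbone extracts spatial feature maps, which
are adaptively average-pooled to a fixed 4x4 grid and projected by a 1x1
convolution into a D-dimensional embedding space, yielding N = 16 spatial
tokens (row-major over the grid: token i sits at grid cell (i // 4, i % 4)).
Learnable positional embeddings are added, a single multi-head self-attention
block with a residual feed-forward refinement produces the final token
representations T2, and the class logits come from layer-normalizing the mean
token and applying one linear map.  T2 is returned alongside the logits
because its per-token L2 norms are the interpretability substrate.

A CNN-only ablation path (backbone -> global average pool -> linear head)
shares the data pipeline and losses with the full model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ModelConfig", "TokenSequence", "ModelOutput", "HybridStageNet",
           "CnnBaseline", "build_model", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    embed_dim is the token embedding dimension D; token_grid is fixed at
    4x4 (N = 16 tokens); heads is the attention head count.  The resnet18
    backbone follows the standard stride-32 schedule (224 -> 512x7x7);
    tiny_cnn is a 3-block strided backbone sized for small inputs and CPU
    training.
    """

    backbone: str = "resnet18"
    pretrained: bool = False
    embed_dim: int = 256
    token_grid: tuple[int, int] = (4, 4)
    heads: int = 4
    transformer_layers: int = 1
    ffn_expansion: int = 4
    n_classes: int = 4
    input_size: int = 224
    in_channels: int = 1
    dropout: float = 0.0
    pos_init_sd: float = 0.02
    tiny_channels: tuple[int, int, int] = (16, 32, 64)
    tiny_bias: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        if tuple(self.token_grid) != (4, 4):
            raise ValueError("token_grid is fixed at 4x4 (16 tokens)")
        if self.backbone not in ("resnet18", "tiny_cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.pretrained:
            raise ValueError(
                "pretrained backbone weights are not available in this "
                "distribution; use pretrained=False (seeded random init)")

    @property
    def n_tokens(self) -> int:
        return self.token_grid[0] * self.token_grid[1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["token_grid"] = list(self.token_grid)
        d["tiny_channels"] = list(self.tiny_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["token_grid"] = tuple(d.get("token_grid", (4, 4)))
        d["tiny_channels"] = tuple(d.get("tiny_channels", (16, 32, 64)))
        return cls(**d)


@dataclass
class TokenSequence:
    """N x D token matrix plus the learnable positional embedding matrix."""

    tokens: Tensor       # (B, N, D)
    positions: Tensor    # (N, D)

    def __post_init__(self):
        if self.tokens.shape[-2:] != self.positions.shape:
            raise ValueError("tokens and positions disagree on (N, D)")
        if not (np.isfinite(self.tokens.data).all()
                and np.isfinite(self.positions.data).all()):
            raise ValueError("non-finite token sequence")


@dataclass
class ModelOutput:
    """Per-image logits, pooled representation and final token embeddings."""

    logits: np.ndarray        # (B, C)
    pooled: np.ndarray        # (B, D)
    final_tokens: np.ndarray  # (B, N, D)

    @property
    def probabilities(self) -> np.ndarray:
        z = self.logits - self.logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    @property
    def predictions(self) -> np.ndarray:
        # np.argmax breaks ties toward the lower class index
        return self.logits.argmax(axis=-1)


# --------------------------------------------------------------------------
# backbones
# --------------------------------------------------------------------------

class TinyCNN(nn.Module):
    """Three conv-relu blocks, stride 2 each (input H -> H/8 feature maps)."""

    def __init__(self, in_ch: int, channels: tuple[int, int, int],
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        c1, c2, c3 = channels
        self.blocks = [
            nn.Conv2d(in_ch, c1, 3, rng, stride=2, padding=1, bias=bias),
            nn.ReLU(),
            nn.Conv2d(c1, c2, 3, rng, stride=2, padding=1, bias=bias),
            nn.ReLU(),
            nn.Conv2d(c2, c3, 3, rng, stride=2, padding=1, bias=bias),
            nn.ReLU(),
        ]
        self.out_channels = c3

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride,
                               padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1,
                               bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = [nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                                   bias=False),
                         nn.BatchNorm2d(out_ch)]

    def forward(self, x: Tensor) -> Tensor:
        identity = x
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        if self.down is not None:
            identity = self.down[1](self.down[0](x))
        return (out + identity).relu()


class ResNet18(nn.Module):
    """Standard 18-layer residual backbone without the classification head.

    Total stride 32: a 224x224 input yields a 512x7x7 feature map.
    """

    def __init__(self, in_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, 64, 7, rng, stride=2, padding=3,
                               bias=False)
        self.bn1 = nn.BatchNorm2d(64)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.layers = []
        ch_in = 64
        for ch_out, stride in ((64, 1), (128, 2), (256, 2), (512, 2)):
            self.layers.append(BasicBlock(ch_in, ch_out, stride, rng))
            self.layers.append(BasicBlock(ch_out, ch_out, 1, rng))
            ch_in = ch_out
        self.out_channels = 512

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool(self.bn1(self.conv1(x)).relu())
        for blk in self.layers:
            x = blk(x)
        return x


def _make_backbone(cfg: ModelConfig, rng: np.random.Generator) -> nn.Module:
    if cfg.backbone == "resnet18":
        # a 3-channel design; single-channel input is replicated in forward
        return ResNet18(3, rng)
    return TinyCNN(cfg.in_channels, cfg.tiny_channels, rng, bias=cfg.tiny_bias)


# --------------------------------------------------------------------------
# transformer block
# --------------------------------------------------------------------------

class MultiHeadSelfAttention(nn.Module):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(D/heads)) V per head."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None   # (B, heads, N, N)

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, N, self.heads, self.head_dim).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        attn = ((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
                ).softmax(axis=-1)
        self.last_attention = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


class TransformerBlock(nn.Module):
    """Residual attention + residual position-wise FFN:

        T1 = T0 + MSA(T0);  T2 = T1 + FFN(T1)
    """

    def __init__(self, dim: int, heads: int, ffn_expansion: int,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ffn1 = nn.Linear(dim, ffn_expansion * dim, rng)
        self.ffn2 = nn.Linear(ffn_expansion * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        t1 = x + self.attn(x)
        return t1 + self.ffn2(self.ffn1(t1).relu())


# --------------------------------------------------------------------------
# full model
# --------------------------------------------------------------------------

class HybridStageNet(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = _make_backbone(cfg, rng)
        self.proj = nn.Conv2d(self.backbone.out_channels, cfg.embed_dim, 1, rng)
        self.pos = Tensor(rng.normal(0.0, cfg.pos_init_sd,
                                     (cfg.n_tokens, cfg.embed_dim)),
                          requires_grad=True)
        self.blocks = [TransformerBlock(cfg.embed_dim, cfg.heads,
                                        cfg.ffn_expansion, rng)
                       for _ in range(cfg.transformer_layers)]
        self.head_norm = nn.LayerNorm(cfg.embed_dim)
        self.head_fc = nn.Linear(cfg.embed_dim, cfg.n_classes, rng)

    # -- pipeline stages (each usable on its own for inspection) ----------
    def _prepare(self, x: np.ndarray | Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.ndim == 3:
            t = t.reshape(t.shape[0], 1, *t.shape[1:])
        if self.cfg.backbone == "resnet18" and t.shape[1] == 1:
            # replicate a single channel for the 3-channel backbone
            t = t + Tensor(np.zeros((1, 3, 1, 1)))
        return t

    def extract_features(self, x: np.ndarray | Tensor) -> Tensor:
        t = self._prepare(x)
        if min(t.shape[2], t.shape[3]) < 32:
            raise ValueError("input must be at least 32x32")
        return self.backbone(t)

    def tokenize(self, feats: Tensor) -> TokenSequence:
        gh, gw = self.cfg.token_grid
        pooled = nn.adaptive_avg_pool2d(feats, (gh, gw))
        z = self.proj(pooled)                                # (B, D, 4, 4)
        b, d = z.shape[0], z.shape[1]
        tokens = z.reshape(b, d, gh * gw).transpose(0, 2, 1)  # row-major tokens
        return TokenSequence(tokens=tokens, positions=self.pos)

    def transformer_forward(self, seq: TokenSequence) -> Tensor:
        t = seq.tokens + seq.positions
        for blk in self.blocks:
            t = blk(t)
        return t

    def classify(self, t2: Tensor) -> tuple[Tensor, Tensor]:
        pooled = t2.mean(axis=1)                              # mean over tokens
        logits = self.head_fc(self.head_norm(pooled))
        return logits, pooled

    # -- public entry points ----------------------------------------------
    def forward_tensors(self, x: np.ndarray | Tensor
                        ) -> tuple[Tensor, Tensor, Tensor]:
        """Differentiable forward: (logits, pooled, final_tokens) Tensors."""
        seq = self.tokenize(self.extract_features(x))
        t2 = self.transformer_forward(seq)
        logits, pooled = self.classify(t2)
        return logits, pooled, t2

    def forward(self, x: np.ndarray | Tensor) -> ModelOutput:
        logits, pooled, t2 = self.forward_tensors(x)
        if not np.isfinite(logits.data).all():
            raise FloatingPointError("non-finite logits")
        return ModelOutput(logits=logits.data, pooled=pooled.data,
                           final_tokens=t2.data)

    def addon_parameter_fraction(self) -> float:
        """Transformer add-on size relative to the backbone."""
        backbone_n = self.backbone.n_parameters()
        addon_n = self.n_parameters() - backbone_n
        return addon_n / backbone_n


class CnnBaseline(nn.Module):
    """Ablation: backbone -> global average pool -> linear head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = _make_backbone(cfg, rng)
        self.head_fc = nn.Linear(self.backbone.out_channels, cfg.n_classes, rng)
        self._prepare = HybridStageNet._prepare.__get__(self)
        self.extract_features = HybridStageNet.extract_features.__get__(self)

    def forward_tensors(self, x) -> tuple[Tensor, Tensor, None]:
        feats = self.extract_features(x)
        pooled = nn.adaptive_avg_pool2d(feats, (1, 1))
        pooled = pooled.reshape(pooled.shape[0], pooled.shape[1])
        return self.head_fc(pooled), pooled, None

    def forward(self, x) -> ModelOutput:
        logits, pooled, _ = self.forward_tensors(x)
        return ModelOutput(logits=logits.data, pooled=pooled.data,
                           final_tokens=np.zeros((logits.shape[0], 0, 0)))


def build_model(cfg: ModelConfig, ablation: bool = False) -> nn.Module:
    return CnnBaseline(cfg) if ablation else HybridStageNet(cfg)


# --------------------------------------------------------------------------
# checkpoints: npz weights + JSON config sidecar
# --------------------------------------------------------------------------

def save_checkpoint(model: nn.Module, path: str | Path,
                    extra: dict | None = None) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    meta = {"config": model.cfg.to_dict(),
            "ablation": isinstance(model, CnnBaseline)}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> tuple[nn.Module, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(meta["config"])
    model = build_model(cfg, ablation=meta.get("ablation", False))
    with np.load(path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model, meta
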