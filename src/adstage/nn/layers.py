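"""Module system and layers built on the autograd Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import (Tensor, adaptive_avg_pool2d, batch_norm2d, conv2d,
                     layer_norm, max_pool2d)

__all__ = ["Module", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm",
           "ReLU", "MaxPool2d", "AdaptiveAvgPool2d", "Sequential"]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # attribute scan keeps the implementation tiny; order is insertion order
    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def _own_params(self):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v

    def named_parameters(self, prefix: str = ""):
        for name, p in self._own_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # buffers (running statistics) are numpy arrays listed in _buffer_names
    _buffer_names: tuple = ()

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict:
        sd = {name: p.data.copy() for name, p in self.named_parameters()}
        sd.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(sd[name], dtype=np.float64)
        for name, buf in self.named_buffers():
            buf[...] = sd["buffer:" + name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Tensor(rng.uniform(-bound, bound, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class AdaptiveAvgPool2d(Module):
    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = tuple(out_hw)

    def forward(self, x: Tensor) -> Tensor:
        return adaptive_avg_pool2d(x, self.out_hw)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
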