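"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine implements exactly the primitives the staging network needs:
broadcast arithmetic, (batched) matmul, reshape/transpose, reductions,
relu, softmax / log-softmax, strided convolution, max/adaptive-average
pooling, layer and batch normalization.  Gradients for every primitive
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "max_pool2d", "adaptive_avg_pool2d",
           "layer_norm", "batch_norm2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __float__(self):
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = bwd
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = bwd
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))
        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        out._backward = bwd
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        logp = z - lse
        out = Tensor(logp, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g - np.exp(logp) * g.sum(axis=axis, keepdims=True))
        out._backward = bwd
        return out


# -- structured primitives ------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation) via im2col.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    B, Cin, H, W = x.shape
    Cout, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                    # (B,Cin,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, Cin * kh * kw)
    wf = w.data.reshape(Cout, -1)                           # (Cout, Cin*kh*kw)
    out_flat = cols @ wf.T                                  # (B, Ho*Wo, Cout)
    if b is not None:
        out_flat = out_flat + b.data
    out_data = out_flat.transpose(0, 2, 1).reshape(B, Cout, Ho, Wo)

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, req, prev)

    def bwd(g):
        gf = g.reshape(B, Cout, Ho * Wo).transpose(0, 2, 1)  # (B, Ho*Wo, Cout)
        if w.requires_grad:
            gw = np.einsum("bpc,bpk->ck", gf, cols).reshape(w.shape)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(gf.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = gf @ wf                                  # (B, Ho*Wo, Cin*kh*kw)
            gcols = gcols.reshape(B, Ho, Wo, Cin, kh, kw)
            gxp = np.zeros_like(xp)
            for a in range(kh):
                for c in range(kw):
                    gxp[:, :, a:a + Ho * stride:stride, c:c + Wo * stride:stride] += \
                        gcols[:, :, :, :, a, c].transpose(0, 3, 1, 2)
            gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
            x._accumulate(gx)
    out._backward = bwd
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    B, C, H, W = x.shape
    pad_val = -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=pad_val)
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kernel) // stride + 1
    Wo = (Wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(B, C, Ho, Wo, kernel * kernel)
    arg = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, arg[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        bi, ci, oi, oj = np.indices((B, C, Ho, Wo))
        ri = oi * stride + arg // kernel
        cj = oj * stride + arg % kernel
        np.add.at(gxp, (bi, ci, ri, cj), g)
        gx = gxp[:, :, padding:padding + H, padding:padding + W] if padding else gxp
        x._accumulate(gx)
    out._backward = bwd
    return out


def _adaptive_bins(n_in: int, n_out: int):
    starts = (np.arange(n_out) * n_in) // n_out
    ends = -(-(np.arange(1, n_out + 1) * n_in) // n_out)   # ceil division
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average pool to a fixed output grid (floor/ceil bin edges)."""
    B, C, H, W = x.shape
    oh, ow = out_hw
    rs, re = _adaptive_bins(H, oh)
    cs, ce = _adaptive_bins(W, ow)
    out_data = np.empty((B, C, oh, ow))
    for i in range(oh):
        for j in range(ow):
            out_data[:, :, i, j] = x.data[:, :, rs[i]:re[i], cs[j]:ce[j]].mean(axis=(2, 3))
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i in range(oh):
            for j in range(ow):
                n = (re[i] - rs[i]) * (ce[j] - cs[j])
                gx[:, :, rs[i]:re[i], cs[j]:ce[j]] += g[:, :, i:i + 1, j:j + 1] / n
        x._accumulate(gx)
    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            n = x.shape[-1]
            gx_hat = g * gamma.data
            gx = inv / n * (n * gx_hat
                            - gx_hat.sum(axis=-1, keepdims=True)
                            - xhat * (gx_hat * xhat).sum(axis=-1, keepdims=True))
            x._accumulate(gx)
    out._backward = bwd
    return out


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channelwise batch normalization for (B, C, H, W); updates running stats in place."""
    c = x.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        n = x.data.size / c
        running_var *= 1 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(gshape)) * inv.reshape(gshape)
    out = Tensor(gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape),
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gy = g * gamma.data.reshape(gshape)
            if training:
                n = x.data.size / c
                gx = inv.reshape(gshape) / n * (
                    n * gy
                    - gy.sum(axis=(0, 2, 3), keepdims=True)
                    - xhat * (gy * xhat).sum(axis=(0, 2, 3), keepdims=True))
            else:
                gx = gy * inv.reshape(gshape)
            x._accumulate(gx)
    out._backward = bwd
    return out
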