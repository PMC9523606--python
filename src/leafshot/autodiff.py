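"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the encoder and metric head need:
broadcast arithmetic, matmul, 3x3 "same" convolution (im2col), ceil-mode
2x2 max-pooling, nearest-neighbour 2x upsampling, center crop/pad,
reductions, relu/sigmoid/exp/log/sqrt, concatenation and slicing —
plus a tiny Module/Parameter system and SGD with momentum.

All data is float32. Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` over a topologically sorted tape. A global
``no_grad()`` context disables taping for cheap inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward(out)
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.shape))
            return fn

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(-g)
            return fn

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            return fn

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accum(
                        _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                    )
            return fn

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g * p * self.data ** (p - 1))
            return fn

        return self._make(self.data ** p, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ g)
            return fn

        return self._make(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g * mask)
            return fn

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        # numerically stable: never exponentiates a positive argument
        x = self.data
        s = np.where(
            x >= 0,
            1.0 / (1.0 + np.exp(-np.abs(x))),
            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))),
        ).astype(np.float32)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g * s * (1.0 - s))
            return fn

        return self._make(s, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g * e)
            return fn

        return self._make(e, (self,), bw)

    def log(self):
        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g / self.data)
            return fn

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        r = np.sqrt(self.data)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g * 0.5 / np.maximum(r, 1e-12))
            return fn

        return self._make(r, (self,), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g.reshape(old))
            return fn

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(out):
            def fn(g):
                if self.requires_grad:
                    self._accum(g.transpose(inv))
            return fn

        return self._make(self.data.transpose(axes), (self,), bw)

    def sum(self, axis=None, keepdims=False):
        shape = self.shape

        def bw(out):
            def fn(g):
                if not self.requires_grad:
                    return
                if axis is None:
                    self._accum(np.broadcast_to(g, shape).astype(np.float32))
                    return
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, shape).astype(np.float32))
            return fn

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max-reduce along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)

        def bw(out):
            def fn(g):
                if not self.requires_grad:
                    return
                grad = np.zeros_like(self.data)
                gg = g if keepdims else np.expand_dims(g, axis)
                np.put_along_axis(
                    grad, np.expand_dims(idx, axis), gg, axis=axis
                )
                self._accum(grad)
            return fn

        return self._make(out_data, (self,), bw)

    def __getitem__(self, key):
        def bw(out):
            def fn(g):
                if self.requires_grad:
                    grad = np.zeros_like(self.data)
                    np.add.at(grad, key, g)
                    self._accum(grad)
            return fn

        return self._make(self.data[key], (self,), bw)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        offsets = np.cumsum([0] + sizes)

        def fn(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out._backward = fn
    return out


# -- spatial primitives (NCHW) --------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """3x3 (or kxk) same-padded stride-1 convolution via im2col.

    x: (N, C, H, W); w: (OC, C, KH, KW); b: (OC,).
    """
    n, c, h, wd = x.shape
    oc, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    wmat = w.data.reshape(oc, c * kh * kw)
    out_data = np.einsum("ok,nkp->nop", wmat, cols2, optimize=True)
    out_data = out_data.reshape(n, oc, oh, ow)
    if b is not None:
        out_data = out_data + b.data.reshape(1, oc, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents

        def fn(g):
            gf = g.reshape(n, oc, oh * ow)
            if w.requires_grad:
                dw = np.einsum("nop,nkp->ok", gf, cols2, optimize=True)
                w._accum(dw.reshape(w.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.einsum("ok,nop->nkp", wmat, gf, optimize=True)
                dcols = dcols.reshape(n, c, kh, kw, oh, ow)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + oh, j : j + ow] += dcols[:, :, i, j]
                x._accum(dxp[:, :, pad : pad + h, pad : pad + wd])

        out._backward = fn
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling, ceil mode (odd edges padded with -inf)."""
    n, c, h, w = x.shape
    ph, pw = (-h) % 2, (-w) % 2
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    oh, ow = xp.shape[2] // 2, xp.shape[3] // 2
    blocks = xp.reshape(n, c, oh, 2, ow, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
    idx = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    out = Tensor(out_data)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)

        def fn(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gp = gflat.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            gp = gp.reshape(n, c, oh * 2, ow * 2)
            x._accum(gp[:, :, :h, :w])

        out._backward = fn
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along both spatial axes."""
    n, c, h, w = x.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(out_data)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)

        def fn(g):
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        out._backward = fn
    return out


def crop_or_pad(x: Tensor, th: int, tw: int) -> Tensor:
    """Center-crop or zero-pad the spatial dims of x to (th, tw)."""
    n, c, h, w = x.shape
    if (h, w) == (th, tw):
        return x
    # crop amounts (nonnegative) and pad amounts (nonnegative)
    ch0 = max((h - th) // 2, 0)
    cw0 = max((w - tw) // 2, 0)
    hh = min(h, th)
    ww = min(w, tw)
    ph0 = max((th - h) // 2, 0)
    pw0 = max((tw - w) // 2, 0)
    out_data = np.zeros((n, c, th, tw), dtype=np.float32)
    out_data[:, :, ph0 : ph0 + hh, pw0 : pw0 + ww] = x.data[
        :, :, ch0 : ch0 + hh, cw0 : cw0 + ww
    ]
    out = Tensor(out_data)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)

        def fn(g):
            grad = np.zeros((n, c, h, w), dtype=np.float32)
            grad[:, :, ch0 : ch0 + hh, cw0 : cw0 + ww] = g[
                :, :, ph0 : ph0 + hh, pw0 : pw0 + ww
            ]
            x._accum(grad)

        out._backward = fn
    return out


# -- module / parameter system ---------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even under no_grad


class Module:
    """Tiny container: tracks Parameters and sub-Modules attribute-wise."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for k in getattr(self, "_buffer_names", ()):
            out.append((prefix + k, getattr(self, k)))
        for name, m in self._modules.items():
            out.extend(m.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({k: b.copy() for k, b in self.buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = {}
        self._collect_buffer_owners("", bufs)
        for k, v in d.items():
            if k in params:
                params[k].data[...] = v
            elif k in bufs:
                owner, attr = bufs[k]
                getattr(owner, attr)[...] = v
            else:
                raise KeyError(f"unknown state entry {k!r}")

    def _collect_buffer_owners(self, prefix, out):
        for k in getattr(self, "_buffer_names", ()):
            out[prefix + k] = (self, k)
        for name, m in self._modules.items():
            m._collect_buffer_owners(prefix + name + ".", out)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 pad: int | None = None, bias: bool = True):
        super().__init__()
        fan_in = in_ch * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.pad = (k // 2) if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        std = float(np.sqrt(2.0 / in_f))
        self.weight = Parameter(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(c) - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.reshape(c) - self.running_var
            )
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class SGD:
    """SGD with classical momentum and decoupled-from-nothing weight decay
    (decay added to the gradient, the convention of torchvision recipes)."""

    def __init__(self, params: Iterable[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
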