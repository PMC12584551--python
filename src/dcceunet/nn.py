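"""Minimal reverse-mode automatic differentiation and CNN layers on NumPy.

This module is the numerical substrate for the segmentation network: a small
tape-based autodiff engine (:class:`Tensor` plus a set of differentiable
primitives) and the layer/optimizer classes built on top of it.  It supports
exactly the operations the architecture needs -- 2-D convolution with dilation,
depthwise strip convolution, batch normalization, 2x2 max pooling, adaptive
average pooling, separable bilinear resizing, elementwise math and reductions
-- all in plain NumPy, so the package has no deep-learning framework
dependency.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order.  All layers are
deterministic given their initialisation RNG and their inputs; inference under
:func:`no_grad` with modules in ``eval()`` mode is bit-reproducible.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Sequence

import numpy as np
import scipy.special

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                # leaf
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if pg is None or not p.requires_grad:
                        continue
                    if p._backward is None:
                        p.grad = pg if p.grad is None else p.grad + pg
                    else:
                        if id(p) in grads:
                            grads[id(p)] = grads[id(p)] + pg
                        else:
                            grads[id(p)] = pg

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=DTYPE))


def _node(data, parents, backward) -> Tensor:
    """Create a graph node if recording is on and any parent needs grad."""
    record = _grad_enabled and any(p.requires_grad for p in parents)
    t = Tensor(data, requires_grad=record)
    if record:
        t._parents = tuple(parents)
        t._backward = backward
    return t


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return _node(out, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return _node(
        out,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** p
    return _node(out, (a,), lambda g: (g * p * a.data ** (p - 1.0),))


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0)
    return _node(out, (a,), lambda g: (g * (a.data > 0),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = scipy.special.expit(a.data)
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return _node(out, (a,), lambda g: (g * out,))


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)
    return _node(out, (a,), lambda g: (g / a.data,))


# ---------------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _node(out, (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def amax(a, axis: int, keepdims: bool = True) -> Tensor:
    """Max reduction; gradient splits evenly among ties."""
    a = as_tensor(a)
    out = a.data.max(axis=axis, keepdims=True)

    def bwd(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        mask = (a.data == out)
        return (g * mask / mask.sum(axis=axis, keepdims=True),)

    return _node(out if keepdims else out.squeeze(axis), (a,), bwd)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    return _node(out, tuple(tensors), lambda g: tuple(np.split(g, splits, axis=axis)))


# ---------------------------------------------------------------------------
# convolution and pooling
# ---------------------------------------------------------------------------

def _im2col(x, kh, kw, stride, pad, dil):
    b, c, h, w = x.shape
    ho = (h + 2 * pad - dil * (kh - 1) - 1) // stride + 1
    wo = (w + 2 * pad - dil * (kw - 1) - 1) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((b, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        hi = i * dil
        for j in range(kw):
            wj = j * dil
            cols[:, :, i, j] = xp[:, :, hi:hi + stride * ho:stride, wj:wj + stride * wo:stride]
    return cols, ho, wo


def _col2im(dcols, xshape, stride, pad, dil):
    b, c, h, w = xshape
    _, _, kh, kw, ho, wo = dcols.shape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        hi = i * dil
        for j in range(kw):
            wj = j * dil
            dxp[:, :, hi:hi + stride * ho:stride, wj:wj + stride * wo:stride] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, full channel connectivity."""
    x, w = as_tensor(x), as_tensor(w)
    co, ci, kh, kw = w.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding, dilation)
    bsz = x.shape[0]
    cols2 = cols.reshape(bsz, ci * kh * kw, ho * wo)
    wmat = w.data.reshape(co, ci * kh * kw)
    out = np.matmul(wmat, cols2).reshape(bsz, co, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    def bwd(g):
        gm = g.reshape(bsz, co, ho * wo)
        dw = np.matmul(gm, cols2.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        dcols = np.matmul(wmat.T, gm).reshape(bsz, ci, kh, kw, ho, wo)
        dx = _col2im(dcols, x.shape, stride, padding, dilation)
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out, parents, bwd)


def strip_conv(x: Tensor, w: Tensor, b: Tensor | None, horizontal: bool) -> Tensor:
    """Depthwise 1xk (horizontal) or kx1 (vertical) convolution, zero padded.

    ``w`` has shape (C, k); each channel is convolved independently along one
    spatial axis, keeping the spatial size.
    """
    x, w = as_tensor(x), as_tensor(w)
    c, k = w.shape
    pad = k // 2
    axis = 3 if horizontal else 2
    padw = [(0, 0)] * 4
    padw[axis] = (pad, pad)
    xp = np.pad(x.data, padw)
    n = x.shape[axis]
    out = np.zeros_like(x.data)
    slicer = [slice(None)] * 4
    for t in range(k):
        slicer[axis] = slice(t, t + n)
        out += w.data[:, t].reshape(1, c, 1, 1) * xp[tuple(slicer)]
    if b is not None:
        out = out + b.data.reshape(1, c, 1, 1)

    def bwd(g):
        gp = np.pad(g, padw)
        dx = np.zeros_like(x.data)
        dw = np.zeros_like(w.data)
        for t in range(k):
            slicer[axis] = slice(t, t + n)
            # dL/dx through tap t: shifted opposite way
            sl_rev = [slice(None)] * 4
            sl_rev[axis] = slice(k - 1 - t, k - 1 - t + n)
            dx += w.data[:, t].reshape(1, c, 1, 1) * gp[tuple(sl_rev)]
            dw[:, t] = (g * xp[tuple(slicer)]).sum(axis=(0, 2, 3))
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out, parents, bwd)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (H and W must be even)."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d needs even spatial size, got {h}x{w}")
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dx.reshape(b, c, h, w),)

    return _node(out, (x,), bwd)


def adaptive_avgpool(x: Tensor, grid: int) -> Tensor:
    """Average pool to a ``grid`` x ``grid`` output (identity if grid >= H,W)."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    gh, gw = min(grid, h), min(grid, w)
    if gh == h and gw == w:
        return x
    hb = [(math.floor(i * h / gh), math.ceil((i + 1) * h / gh)) for i in range(gh)]
    wb = [(math.floor(j * w / gw), math.ceil((j + 1) * w / gw)) for j in range(gw)]
    out = np.empty((b, c, gh, gw), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bwd(g):
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / area
        return (dx,)

    return _node(out, (x,), bwd)


_interp_cache: dict = {}


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel-centre convention)."""
    key = (n_in, n_out, np.dtype(dtype).name)
    m = _interp_cache.get(key)
    if m is not None:
        return m
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[o, lo] += 1.0 - frac
        m[o, hi] += frac
    _interp_cache[key] = m
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of an NCHW tensor to ``out_hw``."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    ho, wo = out_hw
    if ho < 1 or wo < 1:
        raise ValueError("bilinear_resize target size must be >= 1")
    if (ho, wo) == (h, w):
        return x
    mh = _interp_matrix(h, ho, x.data.dtype)
    mw = _interp_matrix(w, wo, x.data.dtype)
    out = np.einsum("oh,bchw,pw->bcop", mh, x.data, mw, optimize=True)

    def bwd(g):
        return (np.einsum("oh,bcop,pw->bchw", mh, g, mw, optimize=True),)

    return _node(out, (x,), bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter / state discovery.

    Children are found in attribute insertion order; plain lists of modules
    are supported, so naming (and hence checkpoints) is deterministic.
    """

    def __init__(self):
        self.training = True

    # children -------------------------------------------------------------
    def _items(self):
        for name, v in self.__dict__.items():
            if isinstance(v, (Parameter, Module)):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, e in enumerate(v):
                    if isinstance(e, (Parameter, Module)):
                        yield f"{name}.{i}", e

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, v in self._items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            else:
                yield from v.named_parameters(full + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, v in self._items():
            if isinstance(v, Module):
                yield from v.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # state ----------------------------------------------------------------
    def _buffers(self):
        """Non-trainable state (overridden by e.g. BatchNorm2d)."""
        return {}

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, v in self._items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[full] = v.data
            else:
                out.update(v.state_dict(full + "."))
        for name, buf in self._buffers().items():
            out[f"{prefix}{name}"] = buf
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, v in self._items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = np.asarray(state[full], dtype=v.data.dtype).reshape(v.data.shape)
            else:
                v.load_state_dict(state, full + ".")
        for name in self._buffers():
            full = f"{prefix}{name}"
            buf = getattr(self, name)
            setattr(self, name, np.asarray(state[full], dtype=buf.dtype).reshape(buf.shape))

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Convolution layer with Kaiming-normal weight initialisation."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 dtype=DTYPE):
        super().__init__()
        self.padding, self.dilation = padding, dilation
        fan_in = cin * k * k
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, k, k)).astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, padding=self.padding, dilation=self.dilation)

    def macs(self, ho: int, wo: int) -> int:
        co, ci, kh, kw = self.weight.shape
        return co * ci * kh * kw * ho * wo


class StripConv(Module):
    """Depthwise 1xk / kx1 strip convolution (channel-independent)."""

    def __init__(self, c: int, k: int, horizontal: bool, rng: np.random.Generator,
                 dtype=DTYPE):
        super().__init__()
        if k % 2 == 0:
            raise ValueError(f"strip kernel must be odd, got {k}")
        self.horizontal = horizontal
        std = math.sqrt(2.0 / k)
        self.weight = Parameter(rng.normal(0.0, std, (c, k)).astype(dtype))
        self.bias = Parameter(np.zeros(c, dtype=dtype))

    def forward(self, x):
        return strip_conv(x, self.weight, self.bias, self.horizontal)

    def macs(self, ho: int, wo: int) -> int:
        c, k = self.weight.shape
        return c * k * ho * wo


class BatchNorm2d(Module):
    """Batch normalization: batch statistics in train mode, running averages
    in eval mode (population variance in both)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=DTYPE):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(c, dtype=dtype))
        self.bias = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        x = as_tensor(x)
        c = x.shape[1]
        if self.training:
            m = tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - m
            v = tmean(xc * xc, axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * v.data.reshape(c))
            xhat = xc * power(v + self.eps, -0.5)
        else:
            m = self.running_mean.reshape(1, c, 1, 1)
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
            xhat = (x - Tensor(m)) * Tensor(inv)
        return xhat * reshape(self.weight, (1, c, 1, 1)) + reshape(self.bias, (1, c, 1, 1))

    def macs(self, ho: int, wo: int) -> int:
        # one multiply-add per element for the affine transform
        return self.weight.data.size * ho * wo


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(lr0: float, epoch: int, total_epochs: int, lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate for epoch ``epoch`` of ``total_epochs``."""
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * epoch / total_epochs))
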