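"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the segmentation network and its
hybrid loss need: broadcasting arithmetic, matmul, the activations, reductions,
shape ops, 2-D convolution with stride/dilation, non-overlapping max pooling,
bilinear upsampling, padding, layer norm and softmax.  Gradients are checked
against central finite differences in the test suite.

Tensors carry ``float32`` data by default (``float64`` inputs are preserved,
which the finite-difference tests rely on).  A global ``no_grad`` context
disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "maxpool2d",
    "upsample_bilinear",
    "pad2d",
    "layer_norm",
    "softmax",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        g = g.astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def _bwd(g, a=self, b=other, out=out):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def _bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
            out._backward = _bwd
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            def _bwd(g, a=self):
                a._accum(g * p * a.data ** (p - 1))
            out._backward = _bwd
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out.requires_grad:
            def _bwd(g, a=self, b=other):
                if a.requires_grad:
                    ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = _bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        out = _make(np.maximum(self.data, 0), (self,))
        if out.requires_grad:
            mask = self.data > 0
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, s=s: a._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, e=e: a._accum(g * e)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out.requires_grad:
            sign = np.sign(self.data)
            out._backward = lambda g, a=self, s=sign: a._accum(g * s)
        return out

    def clip(self, lo: float, hi: float):
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            mask = (self.data >= lo) & (self.data <= hi)
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bwd(g, a=self, axis=axis, keepdims=keepdims):
                if axis is None:
                    a._accum(np.broadcast_to(g, a.data.shape))
                else:
                    if not keepdims:
                        ax = axis if isinstance(axis, tuple) else (axis,)
                        ax = tuple(i % a.data.ndim for i in ax)
                        g = np.expand_dims(g, ax)
                    a._accum(np.broadcast_to(g, a.data.shape))
            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g, a=self, inv=tuple(inv): a._accum(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out.requires_grad:
            def _bwd(g, a=self, key=key):
                full = np.zeros_like(a.data)
                full[key] += g
                a._accum(full)
            out._backward = _bwd
        return out


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bwd(g, ts=tensors, splits=splits, axis=axis):
            pieces = np.split(g, splits, axis=axis)
            for t, piece in zip(ts, pieces):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = _bwd
    return out


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0, dilation=1) -> Tensor:
    """2-D cross-correlation: x (B,C,H,W) with w (F,C,KH,KW)."""
    SH, SW = _pair(stride)
    PH, PW = _pair(padding)
    DH, DW = _pair(dilation)
    F, C, KH, KW = w.data.shape
    if x.data.shape[1] != C:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, weight expects {C}")
    if PH or PW:
        xp = np.zeros((x.data.shape[0], C, x.data.shape[2] + 2 * PH,
                       x.data.shape[3] + 2 * PW), dtype=x.data.dtype)
        xp[:, :, PH:PH + x.data.shape[2], PW:PW + x.data.shape[3]] = x.data
    else:
        xp = x.data
    eKH, eKW = (KH - 1) * DH + 1, (KW - 1) * DW + 1
    if xp.shape[2] < eKH or xp.shape[3] < eKW:
        raise ValueError(
            f"conv2d: padded input {xp.shape[2]}x{xp.shape[3]} smaller than "
            f"effective kernel {eKH}x{eKW}")
    B = xp.shape[0]
    OH = (xp.shape[2] - eKH) // SH + 1
    OW = (xp.shape[3] - eKW) // SW + 1

    def _slice(arr, k, l):
        return arr[:, :, k * DH:k * DH + (OH - 1) * SH + 1:SH,
                   l * DW:l * DW + (OW - 1) * SW + 1:SW]

    # one GEMM per kernel tap: avoids materializing an im2col matrix.
    # For fixed (non-trainable) kernels, all-zero taps contribute nothing.
    taps = [(k, l) for k in range(KH) for l in range(KW)]
    if not w.requires_grad:
        taps = [(k, l) for k, l in taps if np.any(w.data[:, :, k, l])]
    acc = np.zeros((F, B, OH, OW), dtype=xp.dtype)
    for k, l in taps:
        acc += np.tensordot(w.data[:, :, k, l], _slice(xp, k, l), axes=(1, 1))
    out_data = np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out.requires_grad:
        def _bwd(g, x=x, w=w, b=b, xp=xp):
            g = np.ascontiguousarray(g)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                dw = np.empty_like(w.data)
                for k in range(KH):
                    for l in range(KW):
                        dw[:, :, k, l] = np.tensordot(
                            g, _slice(xp, k, l), axes=([0, 2, 3], [0, 2, 3]))
                w._accum(dw)
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for k, l in taps:
                    dkl = np.tensordot(w.data[:, :, k, l], g, axes=(0, 1))
                    _slice(dxp, k, l)[...] += dkl.transpose(1, 0, 2, 3)
                if PH or PW:
                    dxp = dxp[:, :, PH:PH + x.data.shape[2], PW:PW + x.data.shape[3]]
                x._accum(dxp)

        out._backward = _bwd
    return out


def maxpool2d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling (kernel = stride = size)."""
    B, C, H, W = x.data.shape
    if H % size or W % size:
        raise ValueError(f"maxpool2d: spatial dims {H}x{W} not divisible by {size}")
    Ho, Wo = H // size, W // size
    xr = (x.data.reshape(B, C, Ho, size, Wo, size)
          .transpose(0, 1, 2, 4, 3, 5)
          .reshape(B, C, Ho, Wo, size * size))
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bwd(g, x=x, idx=idx):
            g5 = np.zeros((B, C, Ho, Wo, size * size), dtype=g.dtype)
            np.put_along_axis(g5, idx[..., None], g[..., None], axis=-1)
            dx = (g5.reshape(B, C, Ho, Wo, size, size)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(B, C, H, W))
            x._accum(dx)

        out._backward = _bwd
    return out


def _linear_interp_weights(n_in: int, n_out: int):
    # pixel-center alignment (align_corners = False)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, 1.0 - w1, w1


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (B,C,H,W) to spatial ``size``."""
    B, C, H, W = x.data.shape
    OH, OW = size
    ri0, ri1, rw0, rw1 = _linear_interp_weights(H, OH)
    ci0, ci1, cw0, cw1 = _linear_interp_weights(W, OW)
    rows = x.data[:, :, ri0, :] * rw0[None, None, :, None] + \
        x.data[:, :, ri1, :] * rw1[None, None, :, None]
    out_data = rows[:, :, :, ci0] * cw0[None, None, None, :] + \
        rows[:, :, :, ci1] * cw1[None, None, None, :]
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bwd(g, x=x):
            drows = np.zeros((B, C, OH, W), dtype=g.dtype)
            np.add.at(drows, (slice(None), slice(None), slice(None), ci0),
                      g * cw0[None, None, None, :])
            np.add.at(drows, (slice(None), slice(None), slice(None), ci1),
                      g * cw1[None, None, None, :])
            dx = np.zeros((B, C, H, W), dtype=g.dtype)
            np.add.at(dx, (slice(None), slice(None), ri0),
                      drows * rw0[None, None, :, None])
            np.add.at(dx, (slice(None), slice(None), ri1),
                      drows * rw1[None, None, :, None])
            x._accum(dx)

        out._backward = _bwd
    return out


def pad2d(x: Tensor, pad: int, mode: str = "constant") -> Tensor:
    """Pad the two trailing axes of (B,C,H,W) by ``pad`` on each side."""
    B, C, H, W = x.data.shape
    if mode == "constant":
        out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        idx_h = idx_w = None
    elif mode == "replicate":
        idx_h = np.clip(np.arange(-pad, H + pad), 0, H - 1)
        idx_w = np.clip(np.arange(-pad, W + pad), 0, W - 1)
        out_data = x.data[:, :, idx_h[:, None], idx_w[None, :]]
    else:
        raise ValueError(f"unknown pad mode {mode!r}")
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bwd(g, x=x):
            if mode == "constant":
                x._accum(g[:, :, pad:pad + H, pad:pad + W])
            else:
                dx = np.zeros_like(x.data)
                np.add.at(dx, (np.arange(B)[:, None, None, None],
                               np.arange(C)[None, :, None, None],
                               idx_h[None, None, :, None],
                               idx_w[None, None, None, :]), g)
                x._accum(dx)

        out._backward = _bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out.requires_grad:
        def _bwd(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv):
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            if x.requires_grad:
                dxhat = g * gamma.data
                m1 = dxhat.mean(axis=-1, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
                x._accum(inv * (dxhat - m1 - xhat * m2))

        out._backward = _bwd
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    m = x.data.max(axis=-1, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=-1, keepdims=True)
    out = _make(s, (x,))
    if out.requires_grad:
        def _bwd(g, x=x, s=s):
            x._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))

        out._backward = _bwd
    return out
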