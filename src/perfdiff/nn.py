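"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module is a small, self-contained neural-network engine: a ``Tensor``
that records a backward closure per operation, the layer primitives needed
by a conditional U-Net (2-D convolution via im2col, group normalization,
SiLU, dropout, average pooling, nearest-neighbour upsampling, batched
matmul/softmax for spatial attention) and an AdamW optimizer with global
gradient-norm clipping.  Everything is a pure function of its inputs and an
explicit ``numpy.random.Generator``, which keeps training and sampling
bit-reproducible across runs and platforms.

Image tensors are laid out channels-last, (batch, height, width, channels):
with this layout the im2col patch matrix is assembled from contiguous row
copies and 1x1 convolutions and attention reshapes are free, which is what
makes CPU training practical.  Convolution weights keep the conventional
(out_channels, in_channels, k, k) shape.  Only stride-1 square convolutions
and factor-2 pooling/upsampling are implemented — exactly what the U-Net
uses.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _tune_allocator() -> None:
    """Raise glibc's mmap/trim thresholds so the large activation buffers
    allocated every iteration are recycled from the heap instead of being
    mmap'ed and page-zeroed each time (10-20% of training wall time)."""
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)    # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)    # M_TRIM_THRESHOLD
    except Exception:                # non-glibc platform: irrelevant
        pass


_tune_allocator()

__all__ = [
    "Tensor",
    "parameter",
    "no_grad",
    "add",
    "sub",
    "mul",
    "scale",
    "matmul",
    "reshape",
    "transpose",
    "concat",
    "silu",
    "softmax",
    "linear",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2x",
    "group_norm",
    "dropout",
    "l1_loss",
    "kaiming_normal",
    "global_norm_clip",
    "AdamW",
]


class Tensor:
    """An ndarray plus the closure that propagates its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, free_graph: bool = True) -> None:
        """Reverse-mode sweep from this (scalar or any-shape) tensor.

        With ``free_graph`` (default) the tape is dismantled as it is
        consumed: backward closures, parent links and intermediate gradients
        are dropped the moment they have propagated.  The closures form
        reference cycles with their output tensors, so without this the
        garbage collector would hold entire iteration graphs (including
        im2col buffers) alive far longer than needed.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        if self.grad is None:
            self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if free_graph and node._prev:
                node._backward = None
                node._prev = ()
                if node is not self:
                    node.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if not _GRAD_ENABLED:
        return out
    live = [p for p in parents if p.requires_grad or p._prev]
    if live:
        out.requires_grad = True
        out._prev = tuple(live)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data + b.data, (a, b))
    if out._prev:
        def _backward():
            g = out.grad
            if a.requires_grad or a._prev:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad or b._prev:
                b._accumulate(_unbroadcast(g, b.shape))
        out._backward = _backward
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data - b.data, (a, b))
    if out._prev:
        def _backward():
            g = out.grad
            if a.requires_grad or a._prev:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad or b._prev:
                b._accumulate(-_unbroadcast(g, b.shape))
        out._backward = _backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data * b.data, (a, b))
    if out._prev:
        def _backward():
            g = out.grad
            if a.requires_grad or a._prev:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad or b._prev:
                b._accumulate(_unbroadcast(g * a.data, b.shape))
        out._backward = _backward
    return out


def scale(a: Tensor, s: float) -> Tensor:
    s = float(s)  # a NumPy scalar would promote float32 operands to float64
    out = _node(a.data * s, (a,))
    if out._prev:
        def _backward():
            a._accumulate(out.grad * s)
        out._backward = _backward
    return out


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = a.shape
    out = _node(a.data.reshape(shape), (a,))
    if out._prev:
        def _backward():
            a._accumulate(out.grad.reshape(old))
        out._backward = _backward
    return out


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = tuple(int(i) for i in np.argsort(axes))
    out = _node(a.data.transpose(axes), (a,))
    if out._prev:
        def _backward():
            a._accumulate(out.grad.transpose(inv))
        out._backward = _backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._prev:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _backward():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t.requires_grad or t._prev:
                    t._accumulate(g)
        out._backward = _backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; batch dims must broadcast."""
    out = _node(a.data @ b.data, (a, b))
    if out._prev:
        def _backward():
            g = out.grad
            if a.requires_grad or a._prev:
                a._accumulate(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.shape))
            if b.requires_grad or b._prev:
                b._accumulate(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape))
        out._backward = _backward
    return out


def silu(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(a.data * s, (a,))
    if out._prev:
        def _backward():
            a._accumulate(out.grad * (s * (1.0 + a.data * (1.0 - s))))
        out._backward = _backward
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (a,))
    if out._prev:
        def _backward():
            g = out.grad
            a._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))
        out._backward = _backward
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` with ``w`` of shape (out_features, in_features)."""
    out = matmul(x, transpose(w, (1, 0)))
    if b is not None:
        out = add(out, b)
    return out


# ---------------------------------------------------------------------------
# convolution and resampling (channels-last NHWC, stride 1)
# ---------------------------------------------------------------------------

try:  # numba accelerates the im2col gather; the NumPy path is equivalent
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _gather_cols(x, k, pad, cols):  # pragma: no cover - exercised via _im2col
        b, h0, w0, c = x.shape
        h = h0 + 2 * pad - k + 1
        w = w0 + 2 * pad - k + 1
        for bi in range(b):
            for i in range(h):
                for j in range(w):
                    row = (bi * h + i) * w + j
                    off = 0
                    for ki in range(k):
                        ii = i + ki - pad
                        if 0 <= ii < h0:
                            for kj in range(k):
                                jj = j + kj - pad
                                if 0 <= jj < w0:
                                    for cc in range(c):
                                        cols[row, off + cc] = x[bi, ii, jj, cc]
                                else:
                                    for cc in range(c):
                                        cols[row, off + cc] = 0.0
                                off += c
                        else:
                            for cc in range(k * c):
                                cols[row, off + cc] = 0.0
                            off += k * c

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,H,W,C) -> (B*H'*W', k*k*C) patch matrix, patch order (ki, kj, c).

    Padding is folded into the gather (zeros written where the window leaves
    the image), so no padded copy of the input is materialized.
    """
    b, h0, w0, c = x.shape
    h, w = h0 + 2 * pad - k + 1, w0 + 2 * pad - k + 1
    if k == 1 and pad == 0:
        return np.ascontiguousarray(x).reshape(b * h * w, c)
    cols = np.empty((b * h * w, k * k * c), dtype=x.dtype)
    if _HAVE_NUMBA and x.dtype in (np.float32, np.float64):
        _gather_cols(np.ascontiguousarray(x), k, pad, cols)
        return cols
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols6 = cols.reshape(b, h, w, k, k, c)
    for ki in range(k):
        for kj in range(k):
            cols6[:, :, :, ki, kj, :] = x[:, ki:ki + h, kj:kj + w, :]
    return cols


def _weight_mat(w: np.ndarray) -> np.ndarray:
    """(Cout,Cin,k,k) -> (k*k*Cin, Cout) to match the im2col patch order."""
    cout, cin, k, _ = w.shape
    return np.ascontiguousarray(w.transpose(2, 3, 1, 0)).reshape(k * k * cin, cout)


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlate NHWC input, returning (output, patch matrix for reuse)."""
    cout, cin, k, _ = w.shape
    b = x.shape[0]
    h = x.shape[1] + 2 * pad - k + 1
    ww = x.shape[2] + 2 * pad - k + 1
    cols = _im2col(x, k, pad)
    out = cols @ _weight_mat(w)
    return out.reshape(b, h, ww, cout), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | None = None) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with 'same' padding by default.

    ``x`` is (B, H, W, Cin); ``w`` is (Cout, Cin, k, k).
    """
    k = w.data.shape[2]
    if pad is None:
        pad = (k - 1) // 2
    y, cols = _corr2d(x.data, w.data, pad)
    if b is not None:
        y += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)
    if out._prev:
        cout = w.data.shape[0]
        cin = w.data.shape[1]
        def _backward():
            g = out.grad
            gm = g.reshape(-1, cout)
            if w.requires_grad or w._prev:
                dw = (cols.T @ gm).reshape(k, k, cin, cout).transpose(3, 2, 0, 1)
                w._accumulate(dw)
            if b is not None and (b.requires_grad or b._prev):
                b._accumulate(gm.sum(axis=0))
            if x.requires_grad or x._prev:
                wt = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                dx, _ = _corr2d(g, wt, k - 1 - pad)
                x._accumulate(dx)
        out._backward = _backward
    return out


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling; spatial dims must be even."""
    b, h, w, c = x.shape
    y = x.data.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    out = _node(y, (x,))
    if out._prev:
        def _backward():
            g = np.repeat(np.repeat(out.grad, 2, axis=1), 2, axis=2) * 0.25
            x._accumulate(g)
        out._backward = _backward
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out = _node(y, (x,))
    if out._prev:
        b, h, w, c = x.shape
        def _backward():
            g = out.grad.reshape(b, h, 2, w, 2, c).sum(axis=(2, 4))
            x._accumulate(g)
        out._backward = _backward
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Group normalization over channel groups of an NHWC tensor."""
    b, h, w, c = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    cg = c // groups
    n = h * w * cg
    xr = x.data.reshape(b, h * w, groups, cg)
    # einsum reductions: one read for the sum, one for the sum of squares
    mu = np.einsum("bsgc->bg", xr, optimize=True) / n
    ss = np.einsum("bsgc,bsgc->bg", xr, xr, optimize=True) / n
    istd = 1.0 / np.sqrt(np.maximum(ss - mu * mu, 0.0) + eps)
    mu_c = np.repeat(mu, cg, axis=1)[:, None, None, :]        # (B,1,1,C)
    istd_c = np.repeat(istd, cg, axis=1)[:, None, None, :]
    xhat = (x.data.reshape(b, h, w, c) - mu_c) * istd_c
    y = xhat * gamma.data + beta.data
    out = _node(y, (x, gamma, beta))
    if out._prev:
        def _backward():
            g = out.grad
            if gamma.requires_grad or gamma._prev:
                gamma._accumulate(np.einsum("bhwc,bhwc->c", g, xhat, optimize=True))
            if beta.requires_grad or beta._prev:
                beta._accumulate(np.einsum("bhwc->c", g, optimize=True))
            if x.requires_grad or x._prev:
                dxhat = g * gamma.data
                dr = dxhat.reshape(b, h * w, groups, cg)
                xh = xhat.reshape(b, h * w, groups, cg)
                m1 = np.einsum("bsgc->bg", dr, optimize=True) / n
                m2 = np.einsum("bsgc,bsgc->bg", dr, xh, optimize=True) / n
                m1_c = np.repeat(m1, cg, axis=1)[:, None, None, :]
                m2_c = np.repeat(m2, cg, axis=1)[:, None, None, :]
                dx = istd_c * (dxhat - m1_c - xhat * m2_c)
                x._accumulate(dx)
        out._backward = _backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.dtype) / (1.0 - p)
    out = _node(x.data * mask, (x,))
    if out._prev:
        def _backward():
            x._accumulate(out.grad * mask)
        out._backward = _backward
    return out


def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Mean absolute error, returned as a 0-d tensor."""
    diff = pred.data - target.data
    out = _node(np.asarray(np.abs(diff).mean(), dtype=pred.dtype), (pred, target))
    if out._prev:
        n = diff.size
        def _backward():
            g = out.grad * np.sign(diff) / n
            if pred.requires_grad or pred._prev:
                pred._accumulate(g)
            if target.requires_grad or target._prev:
                target._accumulate(-g)
        out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# initialization and optimization
# ---------------------------------------------------------------------------

def kaiming_normal(shape: Sequence[int], fan_in: int, rng: np.random.Generator,
                   gain: float = 1.0, dtype=np.float32) -> np.ndarray:
    std = gain * np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


def global_norm_clip(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum()) for p in params)))
    if total > max_norm and total > 0.0:
        s = max_norm / total
        for p in params:
            p.grad *= s
    return total


class AdamW:
    """Adam with decoupled weight decay.

    ``decay_mask`` marks which parameters receive weight decay (weights yes,
    biases and normalization scales conventionally no).
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 3e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4,
                 decay_mask: Sequence[bool] | None = None):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_mask = list(decay_mask) if decay_mask is not None else [True] * len(self.params)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v, decay in zip(self.params, self.m, self.v, self.decay_mask):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if decay and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= (self.lr * update).astype(p.data.dtype)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
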