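"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides exactly the operator set needed by the video backbone,
the position autoencoder and the attention fusion stack: broadcast
arithmetic, matmul, the usual nonlinearities, softmax, reductions,
same-padded 2D convolution, a non-overlapping temporal convolution,
pooling and nearest-neighbour upsampling.

All 2D convolutions are stride-1 with "same" zero padding and odd kernel
sizes; downsampling is done by pooling and temporal convolution only.
Under that restriction the input gradient of a convolution is itself a
same-padded convolution with the spatially flipped, channel-transposed
kernel, which keeps the backward pass free of scatter operations.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _sfft

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "softmax",
    "conv2d_same",
    "temporal_conv",
    "avg_pool2d",
    "max_pool2d",
    "upsample_nearest",
    "repeat_channels",
    "upsample_time",
    "cross_entropy_logits",
    "mse",
]


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = tuple(parents)

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd ------------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return _add(self, as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return _add(self, as_tensor(other) * -1.0)

    def __rsub__(self, other):
        return _add(as_tensor(other), self * -1.0)

    def __mul__(self, other):
        return _mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return _mul(self, _pow(other, -1.0))

    def __pow__(self, p):
        return _pow(self, p)

    def __matmul__(self, other):
        return _matmul(self, as_tensor(other))

    def __getitem__(self, idx):
        return _getitem(self, idx)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return _transpose(self, axes or None)

    def sum(self, axis=None, keepdims=False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return _sum(self, axis, keepdims) * (1.0 / n)


def _axis_size(shape, axis):
    if isinstance(axis, int):
        axis = (axis,)
    n = 1
    for a in axis:
        n *= shape[a]
    return n


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x))


def _make(data, parents, backward, requires_grad=None):
    if requires_grad is None:
        requires_grad = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=requires_grad, parents=[p for p in parents if p.requires_grad])
    if requires_grad:
        out._backward = backward
    return out


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def _pow(a: Tensor, p) -> Tensor:
    data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1))

    return _make(data, (a,), backward)


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def _getitem(a: Tensor, idx) -> Tensor:
    data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

    return _make(data, (a,), backward)


def _reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def _transpose(a: Tensor, axes) -> Tensor:
    data = a.data.transpose(axes)

    def backward(g):
        if a.requires_grad:
            inv = np.argsort(axes) if axes is not None else None
            a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def _sum(a: Tensor, axis, keepdims) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(data, tuple(tensors), backward)


# ---------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sine(a: Tensor, w0: float = 2.0 * np.pi) -> Tensor:
    """Sinusoidal activation sin(w0 * x) (angular feature embedding)."""
    a = as_tensor(a)
    data = np.sin(w0 * a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * w0 * np.cos(w0 * a.data))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))

    return _make(s, (a,), backward)


# ---------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------

def _pad_hw_last(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Zero-pad axes 1, 2 of a channels-last (B, H, W, C) array."""
    b, h, w, c = x.shape
    out = np.zeros((b, h + 2 * ph, w + 2 * pw, c), dtype=x.dtype)
    out[:, ph:ph + h, pw:pw + w, :] = x
    return out


def _rfft2(a: np.ndarray, s: tuple[int, int]) -> np.ndarray:
    return _sfft.rfft2(a, s=s, axes=(-2, -1))


def _conv2d_raw(x: np.ndarray, w: np.ndarray, xf=None):
    """Same-padded stride-1 cross-correlation. x (B,C,H,W), w (O,C,kh,kw).

    1x1 kernels reduce to a channel matmul; larger (odd) kernels go
    through frequency space, which is far cheaper than im2col for the big
    (13x13, 7x7) kernels this model applies to small feature maps.
    Returns (out, xf) with xf the reusable input transform (None for 1x1).
    """
    o, c, kh, kw = w.shape
    b, _, h, wd = x.shape
    if kh == 1 and kw == 1:
        out = np.tensordot(x, w[:, :, 0, 0], axes=([1], [1]))  # (B,H,W,O)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), None
    s1, s2 = h + kh - 1, wd + kw - 1
    if xf is None:
        xf = _rfft2(x, (s1, s2))
    wf = _rfft2(w[:, :, ::-1, ::-1], (s1, s2))
    # contract channels: (B,1,C,S1,S2) * (1,O,C,S1,S2) -> sum_c -> (B,O,S1,S2)
    yf = (xf[:, None] * wf[None]).sum(axis=2)
    full = _sfft.irfft2(yf, s=(s1, s2), axes=(-2, -1))
    ph, pw = kh // 2, kw // 2
    out = full[:, :, ph:ph + h, pw:pw + wd]
    return np.ascontiguousarray(out).astype(x.dtype, copy=False), xf


def _conv2d_wgrad(x: np.ndarray, g: np.ndarray, kh: int, kw: int,
                  xf=None) -> np.ndarray:
    """Weight gradient of `_conv2d_raw`: gw[o,c,i,j] = sum_b corr(x, g).

    gw[o, c, i, j] = sum_{b,h,w} x[b, c, h+i-ph, w+j-pw] * g[b, o, h, w]
    (zero outside bounds), computed as a batched spatial correlation in
    frequency space.  `xf` may carry the forward pass's input transform.
    """
    b, c, h, wd = x.shape
    o = g.shape[1]
    if kh == 1 and kw == 1:
        gw = np.tensordot(g, x, axes=([0, 2, 3], [0, 2, 3]))  # (O, C)
        return gw[:, :, None, None]
    s1, s2 = h + kh - 1, wd + kw - 1
    if xf is None:
        xf = _rfft2(x, (s1, s2))
    gf = _rfft2(np.ascontiguousarray(g[:, :, ::-1, ::-1]), (s1, s2))
    # contract batch: (B,1,C,S) * (B,O,1,S) -> sum_b -> (O,C,S)
    yf = np.einsum("bcxy,boxy->ocxy", xf, gf) if b > 64 else \
        (xf[:, None] * gf[:, :, None]).sum(axis=0)
    full = _sfft.irfft2(yf, s=(s1, s2), axes=(-2, -1))
    # lag (i - ph, j - pw) sits at circular index (h-1-ph+i, wd-1-pw+j);
    # out-of-range lags hold exact zeros, so modular indexing is safe
    ph, pw = kh // 2, kw // 2
    ri = (h - 1 - ph + np.arange(kh)) % s1
    ci = (wd - 1 - pw + np.arange(kw)) % s2
    gw = full[:, :, ri[:, None], ci[None, :]]
    return np.ascontiguousarray(gw).astype(x.dtype, copy=False)


def conv2d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2D convolution (cross-correlation convention).

    x: (B, C, H, W); w: (O, C, kh, kw) with kh, kw odd; b: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    o, c, kh, kw = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"conv2d_same requires odd kernels, got {kh}x{kw}")
    if x.data.shape[1] != c:
        raise ValueError(
            f"conv2d_same channel mismatch: input has {x.data.shape[1]}, kernel expects {c}"
        )
    data, xf = _conv2d_raw(x.data, w.data)
    if not w.requires_grad:
        xf = None
    if b is not None:
        data = data + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        if w.requires_grad:
            w._accumulate(_conv2d_wgrad(x.data, g, kh, kw, xf=xf))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # input grad = same conv of g with flipped, channel-transposed kernel
            wt = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            x._accumulate(_conv2d_raw(g, wt)[0])

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def temporal_conv(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Non-overlapping temporal convolution (kernel k, stride k, 1x1 spatial).

    x: (B, T, C, H, W); w: (O, k, C); T must be divisible by k.
    Returns (B, T//k, O, H, W).
    """
    x, w = as_tensor(x), as_tensor(w)
    bsz, t, c, h, wd = x.data.shape
    o, k, cin = w.data.shape
    if cin != c:
        raise ValueError(f"temporal_conv channel mismatch: {c} vs {cin}")
    if t % k != 0:
        raise ValueError(f"temporal length {t} not divisible by kernel {k}")
    xg = x.data.reshape(bsz, t // k, k, c, h, wd)
    data = np.tensordot(xg, w.data, axes=([2, 3], [1, 2]))  # (B, T/k, H, W, O)
    data = data.transpose(0, 1, 4, 2, 3)
    if b is not None:
        data = data + b.data.reshape(1, 1, -1, 1, 1)

    def backward(g):
        gt = g.transpose(0, 1, 3, 4, 2)  # (B, T/k, H, W, O)
        if w.requires_grad:
            gw = np.tensordot(gt, xg, axes=([0, 1, 2, 3], [0, 1, 4, 5]))  # (O, k, C)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 3, 4)))
        if x.requires_grad:
            gx = np.tensordot(gt, w.data, axes=([4], [0]))  # (B,T/k,H,W,k,C)
            gx = gx.transpose(0, 1, 4, 5, 2, 3).reshape(x.data.shape)
            x._accumulate(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k average pooling over the trailing two axes (must divide)."""
    x = as_tensor(x)
    *lead, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial dims {h}x{w} not divisible by {k}")
    view = x.data.reshape(*lead, h // k, k, w // k, k)
    data = view.mean(axis=(-3, -1))

    def backward(g):
        if x.requires_grad:
            g2 = np.repeat(np.repeat(g, k, axis=-1), k, axis=-2) / (k * k)
            x._accumulate(g2)

    return _make(data, (x,), backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling over the trailing two axes (must divide)."""
    x = as_tensor(x)
    *lead, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial dims {h}x{w} not divisible by {k}")
    view = x.data.reshape(*lead, h // k, k, w // k, k)
    # move the two pooling axes together: (..., h/k, k, w/k, k) -> (..., h/k, w/k, k*k)
    flat = view.transpose(*range(len(lead)), -4, -2, -3, -1).reshape(*lead, h // k, w // k, k * k)
    arg = flat.argmax(axis=-1)
    data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
            gv = gflat.reshape(*lead, h // k, w // k, k, k)
            gv = gv.transpose(*range(len(lead)), -4, -2, -3, -1)
            x._accumulate(gv.reshape(x.data.shape))

    return _make(data, (x,), backward)


def upsample_nearest(x: Tensor, target_hw: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize of the trailing two axes to `target_hw`."""
    x = as_tensor(x)
    *lead, h, w = x.data.shape
    th, tw = target_hw
    if (th, tw) == (h, w):
        return x
    ri = (np.arange(th) * h // th).astype(np.intp)
    ci = (np.arange(tw) * w // tw).astype(np.intp)
    data = x.data[..., ri[:, None], ci[None, :]]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, (..., ri[:, None], ci[None, :]), g)
            x._accumulate(gx)

    return _make(data, (x,), backward)


def repeat_channels(x: Tensor, r: int, axis: int) -> Tensor:
    """Tile a (channel) axis r times, e.g. to undo a C//r reduction."""
    x = as_tensor(x)
    data = np.repeat(x.data, r, axis=axis)

    def backward(g):
        if x.requires_grad:
            shape = list(x.data.shape)
            shape[axis:axis + 1] = [shape[axis], r]
            gview = g.reshape(
                *x.data.shape[:axis], x.data.shape[axis], r, *x.data.shape[axis + 1:]
            )
            x._accumulate(gview.sum(axis=axis + 1))

    return _make(data, (x,), backward)


def upsample_time(x: Tensor, target_t: int, axis: int = 1) -> Tensor:
    """Nearest-neighbour resize along a temporal axis."""
    x = as_tensor(x)
    t = x.data.shape[axis]
    if t == target_t:
        return x
    idx = (np.arange(target_t) * t // target_t).astype(np.intp)
    data = np.take(x.data, idx, axis=axis)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            sel = [slice(None)] * x.data.ndim
            sel[axis] = idx
            np.add.at(gx, tuple(sel), g)
            x._accumulate(gx)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross entropy of integer labels against raw logits (B, K)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.data.shape[0]
    if n == 0:
        raise ValueError("cross_entropy_logits: empty batch")
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logsumexp
    data = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            probs = np.exp(logp)
            probs[np.arange(n), labels] -= 1.0
            logits._accumulate(g * probs / n)

    return _make(np.asarray(data), (logits,), backward)


def mse(pred: Tensor, target) -> Tensor:
    """Mean squared error against a constant target."""
    pred = as_tensor(pred)
    t = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - t
    data = np.asarray((diff ** 2).mean())

    def backward(g):
        if pred.requires_grad:
            pred._accumulate(g * 2.0 * diff / diff.size)

    return _make(data, (pred,), backward)
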