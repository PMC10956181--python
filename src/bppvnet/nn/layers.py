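"""Parameterised layers built on the autodiff core.

Initialisation is fully seeded: every module draws its weights from a
``numpy.random.Generator`` passed at construction, so a model is a pure
function of its seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    as_tensor,
    avg_pool2d,
    conv2d_same,
    relu,
    temporal_conv,
)

DEFAULT_DTYPE = np.float32


class Module:
    """Lightweight container tracking parameters and submodules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, module has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def parameter(data, dtype=None) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype or DEFAULT_DTYPE), requires_grad=True)


def _he(rng: np.random.Generator, shape, fan_in, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        self.weight = parameter(_he(rng, (in_dim, out_dim), in_dim, dtype), dtype)
        self.bias = parameter(np.zeros(out_dim), dtype)

    def forward(self, x) -> Tensor:
        return as_tensor(x) @ self.weight + self.bias


class Conv2d(Module):
    """Same-padded stride-1 2D convolution layer.

    `support` optionally caps the spatial extent assumed by the He fan-in:
    when a kernel is larger than the feature map it convolves (13x13 on a
    4x4 map), only ~support^2 taps ever see data, and initialising for the
    full kernel area would inflate the activation variance.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True, dtype=None,
                 support: int | None = None):
        dtype = dtype or DEFAULT_DTYPE
        eff = min(kernel, support) if support else kernel
        fan_in = in_ch * eff * eff
        self.kernel = kernel
        self.weight = parameter(
            _he(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype), dtype)
        self.bias = parameter(np.zeros(out_ch), dtype) if bias else None

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 5:  # (B, T, C, H, W): fold time into batch
            b, t, c, h, w = x.shape
            out = conv2d_same(x.reshape(b * t, c, h, w), self.weight, self.bias)
            _, o, oh, ow = out.shape
            return out.reshape(b, t, o, oh, ow)
        return conv2d_same(x, self.weight, self.bias)


class TemporalConv(Module):
    """k x 1 x 1 temporal convolution with stride k (non-overlapping)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        self.kernel = kernel
        self.weight = parameter(
            _he(rng, (out_ch, kernel, in_ch), kernel * in_ch, dtype), dtype)
        self.bias = parameter(np.zeros(out_ch), dtype)

    def forward(self, x) -> Tensor:
        return temporal_conv(x, self.weight, self.bias)


class ResidualBlock(Module):
    """Two same-padded 3x3 convolutions with a residual connection.

    With ``pool=True`` the block halves the spatial resolution first and
    pools the shortcut to match; a 1x1 projection aligns channel counts
    when they differ.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 pool: bool = False, dtype=None):
        self.pool = pool
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, dtype=dtype)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, dtype=dtype)
        self.proj = (Conv2d(in_ch, out_ch, 1, rng, bias=False, dtype=dtype)
                     if in_ch != out_ch else None)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        if self.pool:
            x = avg_pool2d(x, 2)
        shortcut = x if self.proj is None else self.proj(x)
        h = self.conv2(relu(self.conv1(x)))
        return relu(h + shortcut)


class MLP(Module):
    """Fully connected stack with ReLU between layers (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator, dtype=None):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(dims[i], dims[i + 1], rng, dtype=dtype)
                       for i in range(len(dims) - 1)]

    def forward(self, x) -> Tensor:
        h = as_tensor(x)
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = relu(h)
        return h
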