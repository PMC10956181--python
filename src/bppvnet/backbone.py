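"""Temporal-difference video backbone with big-kernel long-term attention.

One 300-frame clip enters as a (T, C, H, W) stack.  The short-term module
computes four frame-difference maps per frame, average-pools them, and
applies a 4x1x1 temporal convolution (stride 4) so the clip is
downsampled to T/4 in time:

    O1     = Conv3D(Avgpool(D(I_i)))
    O2     = Conv3D(I_i) + Upsample(O1)
    Output = ResLayer(O1) + Upsample(ResLayer(O2))

The long-term module reduces channels with a 1x1 convolution, splits the
temporal axis into two equal halves F1, F2 and gates the trunk with a
symmetrised cross-half difference attention map:

    DF(F1, F2) = F1 - Conv_KxK(F2)            (K = 13 big / 3 baseline)
    M1 = Conv_kxk(DF)                          (k = 7 big / 3 baseline)
    M2 = Upsample(Conv_kxk(Maxpool(DF)))
    M  = Sigmoid(Conv(DF + M1 + M2))
    Output = F * (M(F1,F2) + M(F2,F1)) / 2 + F

Feature extraction ends with global mean pooling over time and space and
a linear projection to the shared embedding dimension d.  Weights are
shared across the six head positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, as_tensor

KERNEL_MODES = {
    "big": {"df_kernel": 13, "gate_kernel": 7},
    "baseline": {"df_kernel": 3, "gate_kernel": 3},
}


@dataclass(frozen=True)
class BackboneConfig:
    kernel_mode: str = "big"
    d: int = 32                 # embedding dimension (shared with positions)
    base_channels: int = 8      # channel width after the short-term module
    stage_blocks: int = 2       # residual blocks per stage
    stages: int = 2
    reduction: int = 2          # channel reduction r in the long-term split
    frame_size: tuple[int, int] = (64, 64)
    in_channels: int = 1

    def __post_init__(self):
        if self.kernel_mode not in KERNEL_MODES:
            raise ValueError(
                f"unknown kernel_mode {self.kernel_mode!r}; "
                f"valid: {sorted(KERNEL_MODES)}")
        if self.base_channels % self.reduction:
            raise ValueError("base_channels must be divisible by reduction")

    @property
    def kernels(self) -> dict[str, int]:
        return KERNEL_MODES[self.kernel_mode]


# ---------------------------------------------------------------------
# frame differences
# ---------------------------------------------------------------------

def frame_difference(stack: np.ndarray, i: int) -> np.ndarray:
    """Dynamic feature maps of frame i: [D_-2, D_-1, D_1, D_2].

    D_k = I_{i+k} - I_i with clamped replication at the clip boundary.
    `stack` is (T, C, H, W); returns (4, C, H, W).
    """
    stack = np.asarray(stack)
    t = stack.shape[0]
    if t < 5:
        raise ValueError(f"frame_difference needs T >= 5 frames, got {t}")
    maps = []
    for k in (-2, -1, 1, 2):
        j = min(max(i + k, 0), t - 1)
        maps.append(stack[j].astype(np.float64) - stack[i].astype(np.float64))
    return np.stack(maps)


def frame_difference_all(stack: np.ndarray) -> np.ndarray:
    """Vectorised frame differences for every frame.

    (T, C, H, W) -> (T, 4*C, H, W): the four offset maps are stacked along
    the channel axis in offset order (-2, -1, 1, 2).
    """
    stack = np.asarray(stack)
    t = stack.shape[0]
    if t < 5:
        raise ValueError(f"frame_difference_all needs T >= 5 frames, got {t}")
    idx = np.arange(t)
    parts = []
    for k in (-2, -1, 1, 2):
        j = np.clip(idx + k, 0, t - 1)
        parts.append(stack[j] - stack)
    return np.concatenate(parts, axis=1)


def frame_difference_batch(stacks: np.ndarray) -> np.ndarray:
    """Batched frame differences: (B, T, C, H, W) -> (B, T, 4*C, H, W)."""
    t = stacks.shape[1]
    if t < 5:
        raise ValueError(f"frame_difference_batch needs T >= 5 frames, got {t}")
    idx = np.arange(t)
    parts = []
    for k in (-2, -1, 1, 2):
        j = np.clip(idx + k, 0, t - 1)
        parts.append(stacks[:, j] - stacks)
    return np.concatenate(parts, axis=2)


# ---------------------------------------------------------------------
# short-term module
# ---------------------------------------------------------------------

class ShortTermModule(nn.Module):
    """Frame-difference motion branch + appearance branch, fused.

    Input (B, T, C, H, W) float, T divisible by 4.  Output
    (B, T/4, base_channels, H/2, W/2).
    """

    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 dtype=None):
        c_in = config.in_channels
        c = config.base_channels
        self.config = config
        # motion branch: 4 diff maps as channels, avg-pooled, temporal conv
        self.conv3d_diff = nn.TemporalConv(4 * c_in, c, 4, rng, dtype=dtype)
        # appearance branch: raw frames, temporal conv
        self.conv3d_app = nn.TemporalConv(c_in, c, 4, rng, dtype=dtype)
        self.res_motion = [nn.ResidualBlock(c, c, rng, dtype=dtype)
                           for _ in range(config.stage_blocks)]
        self.res_app = [nn.ResidualBlock(c, c, rng, pool=(i == 0), dtype=dtype)
                        for i in range(config.stage_blocks)]
        #: when False the branch activations are skipped (linearity probes)
        self.use_activation = True

    def branches(self, x) -> tuple[Tensor, Tensor]:
        """The two pre-ResLayer branches (O1, O2) of the module."""
        x = as_tensor(x)
        b, t, c, h, w = x.shape
        if t % 4:
            raise ValueError(f"short_term requires T divisible by 4, got T={t}")
        # frame differences carry no parameters upstream: computed outside
        # the autograd graph
        diffs = Tensor(frame_difference_batch(x.data).reshape(b * t, 4 * c, h, w))
        pooled = nn.avg_pool2d(diffs, 2).reshape(b, t, 4 * c, h // 2, w // 2)
        act = nn.relu if self.use_activation else (lambda z: z)
        o1 = act(self.conv3d_diff(pooled))                # (B, T/4, C, H/2, W/2)
        app = act(self.conv3d_app(x))                     # (B, T/4, C, H, W)
        o2 = app + _upsample_to(o1, app)
        return o1, o2

    def forward(self, x) -> Tensor:
        o1, o2 = self.branches(x)
        r1 = _apply_blocks(self.res_motion, o1)           # (B, T/4, C, H/2, W/2)
        r2 = _apply_blocks(self.res_app, o2)              # (B, T/4, C, H/2, W/2)
        return r1 + _upsample_to(r2, r1)


def _apply_blocks(blocks, x: Tensor) -> Tensor:
    b, t = x.shape[:2]
    h = x.reshape(b * t, *x.shape[2:])
    for blk in blocks:
        h = blk(h)
    return h.reshape(b, t, *h.shape[1:])


def _upsample_to(x: Tensor, ref: Tensor) -> Tensor:
    """Nearest-neighbour resize of x's spatial dims to match ref's."""
    return nn.upsample_nearest(x, (ref.shape[-2], ref.shape[-1]))


# ---------------------------------------------------------------------
# long-term module
# ---------------------------------------------------------------------

def split_halves(t: int) -> tuple[slice, slice]:
    """Index ranges of the two temporal halves with T1 = T2 = ceil(T/2).

    For odd T the halves overlap by one central frame.
    """
    t1 = -(-t // 2)  # ceil
    return slice(0, t1), slice(t - t1, t)


class LongTermModule(nn.Module):
    """Cross-half difference gating with configurable (big) kernels."""

    def __init__(self, channels: int, config: BackboneConfig,
                 rng: np.random.Generator, dtype=None,
                 support: int | None = None):
        if channels % config.reduction:
            raise ValueError(
                f"channels {channels} not divisible by reduction {config.reduction}")
        k = config.kernels
        self.reduction = config.reduction
        cr = channels // config.reduction
        half = max(1, support // 2) if support else None
        self.reduce = nn.Conv2d(channels, cr, 1, rng, dtype=dtype)
        self.conv_df = nn.Conv2d(cr, cr, k["df_kernel"], rng, dtype=dtype,
                                 support=support)
        self.conv_m1 = nn.Conv2d(cr, cr, k["gate_kernel"], rng, dtype=dtype,
                                 support=support)
        self.conv_m2 = nn.Conv2d(cr, cr, k["gate_kernel"], rng, dtype=dtype,
                                 support=half)
        self.conv_out = nn.Conv2d(cr, cr, 1, rng, dtype=dtype)

    def split_channels(self, f: Tensor) -> tuple[Tensor, Tensor]:
        """1x1 channel reduction, then temporal split into equal halves."""
        f = as_tensor(f)
        reduced = _apply_time(self.reduce, f)
        s1, s2 = split_halves(f.shape[1])
        return reduced[:, s1], reduced[:, s2]

    def gate(self, f1: Tensor, f2: Tensor) -> Tensor:
        """Attention map M(F1, F2) in (0, 1), same shape as F1."""
        f1, f2 = as_tensor(f1), as_tensor(f2)
        if f1.shape != f2.shape:
            raise ValueError(
                f"gate: split halves differ in shape {f1.shape} vs {f2.shape}")
        df = f1 - _apply_time(self.conv_df, f2)
        m1 = _apply_time(self.conv_m1, df)
        b, t, c, h, w = df.shape
        df_flat = df.reshape(b * t, c, h, w)
        if h % 2 or w % 2:
            raise ValueError(
                f"gate: spatial dims {h}x{w} must be even for Maxpool/Upsample")
        m2 = nn.upsample_nearest(
            self.conv_m2(nn.max_pool2d(df_flat, 2)), (h, w)).reshape(df.shape)
        return nn.sigmoid(_apply_time(self.conv_out, df + m1 + m2))

    def forward(self, f) -> Tensor:
        """Output = F * (M(F1,F2) + M(F2,F1)) / 2 + F (gate broadcast to F).

        Both argument orders are evaluated in one batched pass through the
        gate convolutions (they share weights), then averaged.
        """
        f = as_tensor(f)
        f1, f2 = self.split_channels(f)
        b = f.shape[0]
        both = self.gate(nn.concat([f1, f2], axis=0), nn.concat([f2, f1], axis=0))
        m = (both[:b] + both[b:]) * 0.5
        gate_full = self._broadcast_gate(m, f)
        return f * gate_full + f

    def _broadcast_gate(self, m: Tensor, f: Tensor) -> Tensor:
        # gate is (B, T1, C/r, H, W): tile channels back to C and resize
        # the temporal axis to T by nearest neighbour
        g = nn.repeat_channels(m, self.reduction, axis=2)
        return nn.upsample_time(g, f.shape[1], axis=1)


def _apply_time(layer, x: Tensor) -> Tensor:
    """Apply a 2D conv layer over a (B, T, C, H, W) tensor."""
    return layer(x)  # Conv2d handles 5D by folding time into batch


# ---------------------------------------------------------------------
# full backbone
# ---------------------------------------------------------------------

class EyeMovementBackbone(nn.Module):
    """300-frame clip -> d-dimensional eye-movement feature vector."""

    def __init__(self, config: BackboneConfig = BackboneConfig(),
                 seed: int = 0, dtype=None):
        rng = np.random.default_rng(seed)
        self.config = config
        self.short_term = ShortTermModule(config, rng, dtype=dtype)
        c = config.base_channels
        self.stages = []
        self.long_terms = []
        for s in range(config.stages):
            blocks = [nn.ResidualBlock(c, c, rng, pool=(s > 0 and i == 0),
                                       dtype=dtype)
                      for i in range(config.stage_blocks)]
            self.stages.append(blocks)
            # feature-map size at this stage: frame/2 after short_term,
            # halved once per later stage - caps big-kernel init fan-in
            stage_size = max(1, config.frame_size[0] // (2 ** (1 + s)))
            self.long_terms.append(LongTermModule(c, config, rng, dtype=dtype,
                                                  support=stage_size))
        self.proj = nn.Linear(c, config.d, rng, dtype=dtype)

    def features(self, clips) -> Tensor:
        """(B, T, C, H, W) normalised clips -> (B, d) feature vectors."""
        h = self.short_term(clips)
        for blocks, lt in zip(self.stages, self.long_terms):
            h = _apply_blocks(blocks, h)
            h = lt(h)
        pooled = h.mean(axis=(1, 3, 4))  # global over T, H, W -> (B, C)
        return self.proj(pooled)

    def forward(self, clips) -> Tensor:
        return self.features(clips)


def set_kernel_mode(config: BackboneConfig, mode: str) -> BackboneConfig:
    """Return a config with the requested kernel mode (big | baseline)."""
    if mode not in KERNEL_MODES:
        raise ValueError(f"unknown kernel mode {mode!r}; valid: {sorted(KERNEL_MODES)}")
    from dataclasses import replace

    return replace(config, kernel_mode=mode)


def extract_eye_features(backbone: EyeMovementBackbone, clip: np.ndarray) -> np.ndarray:
    """Feature vector of a single standardized clip (T, H, W) in [0, 255]."""
    x = prepare_clips(clip[None])
    return backbone.features(x).data[0]


def prepare_clips(clips: np.ndarray) -> np.ndarray:
    """uint8 clips (B, T, H, W[, 3]) -> float (B, T, C, H, W) in [0, 1]."""
    clips = np.asarray(clips)
    if clips.ndim == 4:
        clips = clips[:, :, None, :, :]
    elif clips.ndim == 5:
        clips = np.moveaxis(clips, -1, 2)
    else:
        raise ValueError(f"expected 4D or 5D clips, got shape {clips.shape}")
    return (clips.astype(nn.DEFAULT_DTYPE)) / 255.0
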