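"""Head-position encoding and gaze-coordinate pre-training.

A chair posture is a (main-axis, auxiliary-axis) rotation pair in
(-360, 360) degrees, normalised by 360 into (-1, 1)^2.  A three-layer FC
encoder maps it to a d-dimensional feature vector; a two-layer FC decoder
maps the feature back to the 3D Cartesian coordinates of a synthetic
line-of-sight orientation vector:

    x = cos(phi)
    y = sin(theta) +/- sqrt((1 - cos^2(phi)) / (1 + tan^2(theta)))
    z = cos(theta) +/- tan(theta) * sqrt((1 - cos^2(phi)) / (1 + tan^2(theta)))

with theta, phi in radians in (-2*pi, 2*pi) and the same sign branch used
for y and z.  Pre-training regresses decoder output onto these targets;
the same reconstruction error serves as a penalty term during joint
training of the full classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocess import normalize_position

SINGULARITY_EPS = 1e-3
"""Guard radius (radians) around odd multiples of pi/2 where tan diverges."""


@dataclass(frozen=True)
class GazeCoordinate:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=np.float64)


def default_branch(theta: float, phi: float) -> int:
    """Sign-branch convention: sign(sin(phi) * cos(theta)), +1 at zero.

    This choice makes the y and z targets analytically smooth
    (y = sin t + sin p cos t, z = cos t + sin p sin t), which the
    regression pre-training needs; any fixed-in-theta rule leaves a jump
    discontinuity in z across the tangent singularities.
    """
    s = math.sin(phi) * math.cos(theta)
    return -1 if s < 0 else 1


def near_singularity(theta: float, eps: float = SINGULARITY_EPS) -> bool:
    """True when theta is within eps of an odd multiple of pi/2."""
    return abs(math.cos(theta)) < math.sin(eps)


def gaze_coordinates(theta: float, phi: float, branch: int | None = None) -> GazeCoordinate:
    """Line-of-sight 3D coordinates for main-axis theta, auxiliary-axis phi.

    Angles are radians in (-2*pi, 2*pi).  `branch` selects the +/- sign
    applied consistently to y and z; by default it follows
    sign(sin(phi) * cos(theta)) so that the coordinates vary smoothly.

    Raises ValueError outside the domain or within the tangent-singularity
    guard band around theta = +/- pi/2, +/- 3*pi/2.
    """
    for name, v in (("theta", theta), ("phi", phi)):
        if not -2 * math.pi < v < 2 * math.pi:
            raise ValueError(f"{name} must lie in (-2*pi, 2*pi), got {v}")
    if near_singularity(theta):
        raise ValueError(
            f"theta={theta} is within {SINGULARITY_EPS} rad of a tan singularity")
    if branch is None:
        branch = default_branch(theta, phi)
    if branch not in (-1, 1):
        raise ValueError(f"branch must be +1 or -1, got {branch}")
    tan_t = math.tan(theta)
    root = math.sqrt((1.0 - math.cos(phi) ** 2) / (1.0 + tan_t ** 2))
    x = math.cos(phi)
    y = math.sin(theta) + branch * root
    z = math.cos(theta) + branch * tan_t * root
    return GazeCoordinate(x, y, z)


def gaze_targets(angles_rad: np.ndarray) -> np.ndarray:
    """Vector of gaze coordinates for an (n, 2) array of (theta, phi)."""
    return np.stack([gaze_coordinates(t, p).as_array() for t, p in angles_rad])


def sample_angle_pairs(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n (theta, phi) pairs uniformly over (-2*pi, 2*pi)^2,
    resampling theta draws that fall inside the singularity guard."""
    out = np.empty((n, 2), dtype=np.float64)
    for i in range(n):
        theta = rng.uniform(-2 * math.pi, 2 * math.pi)
        while near_singularity(theta):
            theta = rng.uniform(-2 * math.pi, 2 * math.pi)
        out[i] = (theta, rng.uniform(-2 * math.pi, 2 * math.pi))
    return out


# ---------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------

class PositionEncoder(nn.Module):
    """Three FC layers: normalised (theta, phi) -> d-dim feature vector.

    The first layer uses a sinusoidal activation (sin(2*pi*x), an angular
    feature embedding): the gaze targets are trigonometric polynomials of
    the de-normalised angles, which a periodic first layer can represent
    exactly while plain ReLU stacks generalise poorly from 200 samples.
    """

    def __init__(self, d: int = 128, rng: np.random.Generator | None = None,
                 hidden: tuple[int, int] = (64, 128), dtype=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d = d
        self.l1 = nn.Linear(2, hidden[0], rng, dtype=dtype)
        self.l2 = nn.Linear(hidden[0], hidden[1], rng, dtype=dtype)
        self.l3 = nn.Linear(hidden[1], d, rng, dtype=dtype)

    def forward(self, x) -> nn.Tensor:
        return self.l3(nn.relu(self.l2(nn.sine(self.l1(x)))))


class PositionDecoder(nn.Module):
    """Two FC layers: d-dim feature -> 3D gaze-coordinate estimate."""

    def __init__(self, d: int = 128, rng: np.random.Generator | None = None,
                 hidden: int = 64, dtype=None):
        rng = rng if rng is not None else np.random.default_rng(1)
        self.net = nn.MLP([d, hidden, 3], rng, dtype=dtype)

    def forward(self, x) -> nn.Tensor:
        return self.net(x)


@dataclass
class PretrainResult:
    """`mae` is the fit error on the pre-training vectors (the quantity the
    training curve tracks); `holdout_mae` is measured on fresh samples and
    is intrinsically larger (200 points cannot pin the full angular domain
    to fit precision)."""

    encoder: PositionEncoder
    decoder: PositionDecoder
    mae: float
    holdout_mae: float
    history: list[dict] = field(default_factory=list)  # epoch, loss, mae


def angles_deg_to_model_inputs(angles_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degrees (n, 2) -> (normalised inputs (n, 2), radian targets (n, 3))."""
    norm = np.stack([normalize_position(t, p) for t, p in angles_deg])
    targets = gaze_targets(np.deg2rad(angles_deg))
    return norm, targets


def reconstruction_penalty(
    positions_norm: np.ndarray,
    targets: np.ndarray,
    encoder: PositionEncoder,
    decoder: PositionDecoder,
) -> nn.Tensor:
    """MSE between decode(encode(v)) and the gaze-coordinate targets.

    `positions_norm` is an (n, 2) batch of normalised position vectors,
    `targets` the matching (n, 3) gaze coordinates.  Differentiable
    through both networks; order-invariant over the batch.
    """
    positions_norm = np.asarray(positions_norm, dtype=np.float64)
    if positions_norm.ndim != 2 or positions_norm.shape[0] == 0:
        raise ValueError("reconstruction_penalty: batch must be non-empty (n, 2)")
    pred = decoder(encoder(positions_norm.astype(nn.DEFAULT_DTYPE)))
    return nn.mse(pred, np.asarray(targets))


def pretrain_autoencoder(
    n_samples: int = 200,
    epochs: int = 100,
    seed: int = 0,
    d: int = 128,
    lr: float = 0.005,
    batch_size: int = 5,
    n_eval: int = 200,
) -> PretrainResult:
    """Pre-train the autoencoder on random postures against gaze targets.

    Samples `n_samples` angle pairs uniformly (resampling near tangent
    singularities), trains with minibatch Adam under a half-cosine decayed
    learning rate, and reports the fit MAE on the pre-training vectors
    plus a held-out MAE on `n_eval` fresh seeded samples.  Aborts on a
    non-finite loss.
    """
    rng = np.random.default_rng(seed)
    train_rad = sample_angle_pairs(n_samples, rng)
    train_deg = np.rad2deg(train_rad)
    x_train, y_train = angles_deg_to_model_inputs(train_deg)

    eval_rad = sample_angle_pairs(n_eval, np.random.default_rng(seed + 777_001))
    x_eval, y_eval = angles_deg_to_model_inputs(np.rad2deg(eval_rad))

    init_rng = np.random.default_rng(seed + 13)
    encoder = PositionEncoder(d=d, rng=init_rng)
    decoder = PositionDecoder(d=d, rng=init_rng)
    opt = nn.Adam(encoder.parameters() + decoder.parameters(), lr=lr)

    history: list[dict] = []
    x32 = x_train.astype(nn.DEFAULT_DTYPE)
    shuffle_rng = np.random.default_rng(seed + 99)
    for epoch in range(epochs):
        opt.lr = nn.sine_decay_lr(lr, epoch, epochs)
        order = shuffle_rng.permutation(n_samples)
        epoch_losses = []
        for start in range(0, n_samples, batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            loss = nn.mse(decoder(encoder(x32[idx])), y_train[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"pre-training diverged at epoch {epoch}: loss={value}")
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        history.append({
            "epoch": epoch, "loss": float(np.mean(epoch_losses)),
            "mae": evaluate_mae(encoder, decoder, x_train, y_train)})
    return PretrainResult(
        encoder=encoder, decoder=decoder,
        mae=evaluate_mae(encoder, decoder, x_train, y_train),
        holdout_mae=evaluate_mae(encoder, decoder, x_eval, y_eval),
        history=history)


def evaluate_mae(encoder: PositionEncoder, decoder: PositionDecoder,
                 x: np.ndarray, y: np.ndarray) -> float:
    pred = decoder(encoder(x.astype(nn.DEFAULT_DTYPE))).data
    return float(np.abs(pred - y).mean())


def save_pretrain_curve(result: PretrainResult, path: str) -> None:
    """Log the pre-training curve as CSV (epoch, loss, mae)."""
    import pandas as pd

    pd.DataFrame(result.history).to_csv(path, index=False)
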