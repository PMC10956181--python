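"""Cross-attention fusion of eye-movement and head-position features.

Scaled dot-product attention (softmax(Q K^T / sqrt(d_k)) V) drives a
cross -> self -> cross stack applied per head position:

    Output = A_cross(A_self(A_cross(F_e, F_p)), A_self(A_cross(F_p, F_e)))

where A_cross(a, b) uses a as Query and b as key/value.  The six fused
per-position vectors are concatenated into one case-level vector and
classified by a single fully connected layer.

All ablation fusion variants are provided: ``cross`` (the stack above),
``self`` (the same stack fed the eye vector on both sides, i.e. pure
self-attention), ``concat`` (no attention), ``weighted_sum`` (trainable
scalar-weighted sum), ``weighted_sum_self`` and ``none`` (eye features
passed through, unimodal).

Feature vectors are treated as token sequences: dimension d is split into
``tokens`` tokens of d/tokens channels (default 1 token).  Projections
are bias-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, as_tensor

VARIANTS = ("cross", "self", "concat", "weighted_sum", "weighted_sum_self", "none")


@dataclass(frozen=True)
class AttentionConfig:
    """Fusion configuration.

    ``variant="self"`` means self-attention over the joint eye+position
    token sequence when ``multimodal=True`` and the eye-only stack of
    Fig-9 style ablations when ``multimodal=False``.
    """

    d: int = 32
    tokens: int = 1
    variant: str = "cross"
    multimodal: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {VARIANTS}")
        if self.tokens <= 0 or self.d % self.tokens:
            raise ValueError(
                f"d={self.d} must be divisible by a positive token count "
                f"{self.tokens}")
        if not self.multimodal and self.variant not in ("self", "none"):
            raise ValueError(
                f"unimodal input supports variants 'self'/'none', got {self.variant!r}")

    @property
    def d_k(self) -> int:
        return self.d // self.tokens

    @property
    def fused_dim(self) -> int:
        if self.variant == "concat" or (self.variant == "self" and self.multimodal):
            per_position = 2 * self.d
        else:
            per_position = self.d
        return 6 * per_position


def scaled_attention(q, k, v) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with row-wise softmax.

    Accepts (..., n_q, d_k) queries, (..., n_k, d_k) keys and
    (..., n_k, d_v) values; leading batch axes broadcast.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(
            f"query dim {q.shape[-1]} != key dim {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(
            f"key count {k.shape[-2]} != value count {v.shape[-2]}")
    d_k = q.shape[-1]
    kt = k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)
    weights = nn.softmax((q @ kt) * (1.0 / np.sqrt(d_k)), axis=-1)
    return weights @ v


class AttentionLayer(nn.Module):
    """Single-head attention with learned bias-free Q/K/V projections."""

    def __init__(self, d_k: int, rng: np.random.Generator, dtype=None):
        dtype = dtype or nn.DEFAULT_DTYPE
        self.d_k = d_k

        def proj():
            w = (rng.standard_normal((d_k, d_k)) / np.sqrt(d_k)).astype(dtype)
            return nn.parameter(w, dtype)

        self.wq, self.wk, self.wv = proj(), proj(), proj()

    def forward(self, query, keyvalue=None) -> Tensor:
        """Cross-attention of query tokens against key/value tokens.

        With ``keyvalue=None`` this is self-attention.  Shapes are
        (..., n_tokens, d_k).
        """
        query = as_tensor(query)
        keyvalue = query if keyvalue is None else as_tensor(keyvalue)
        return scaled_attention(query @ self.wq, keyvalue @ self.wk,
                                keyvalue @ self.wv)


class CrossBlock(nn.Module):
    """The cross -> self -> cross stack applied to one position's pair."""

    def __init__(self, config: AttentionConfig, rng: np.random.Generator,
                 dtype=None):
        self.config = config
        self.cross_in = AttentionLayer(config.d_k, rng, dtype)
        self.self_attn = AttentionLayer(config.d_k, rng, dtype)
        self.cross_out = AttentionLayer(config.d_k, rng, dtype)

    def forward(self, f_e, f_p) -> Tensor:
        """(..., tokens, d_k) eye and position tokens -> fused tokens."""
        f_e, f_p = as_tensor(f_e), as_tensor(f_p)
        if f_e.shape != f_p.shape:
            raise ValueError(
                f"cross_block: eye {f_e.shape} and position {f_p.shape} "
                "token shapes must match")
        branch_e = self.self_attn(self.cross_in(f_e, f_p))
        branch_p = self.self_attn(self.cross_in(f_p, f_e))
        # final merge: eye-side branch as Query, position-side as key/value
        return self.cross_out(branch_e, branch_p)


class FusionModule(nn.Module):
    """Per-position fusion + cross-position concatenation + FC classifier."""

    def __init__(self, config: AttentionConfig = AttentionConfig(),
                 n_classes: int = 6, seed: int = 0, dtype=None):
        rng = np.random.default_rng(seed)
        self.config = config
        v = config.variant
        self.cross_block = (
            CrossBlock(config, rng, dtype)
            if v == "cross" or (v == "self" and not config.multimodal) else None)
        self.self_only = (
            AttentionLayer(config.d_k, rng, dtype)
            if v == "weighted_sum_self" or (v == "self" and config.multimodal)
            else None)
        if v in ("weighted_sum", "weighted_sum_self"):
            self.w_e = nn.parameter(np.array(0.5), dtype)
            self.w_p = nn.parameter(np.array(0.5), dtype)
        else:
            self.w_e = self.w_p = None
        self.classifier = nn.Linear(config.fused_dim, n_classes, rng, dtype=dtype)
        # zero-init head: training starts from uniform class probabilities
        self.classifier.weight.data[:] = 0.0

    # -- token helpers -------------------------------------------------
    def _tokens(self, x: Tensor) -> Tensor:
        """(B, 6, d) -> (B, 6, tokens, d_k)."""
        b, p, d = x.shape
        return x.reshape(b, p, self.config.tokens, self.config.d_k)

    def _flatten(self, x: Tensor) -> Tensor:
        """(B, 6, tokens, d_k) -> (B, 6 * d)."""
        b = x.shape[0]
        return x.reshape(b, -1)

    # -- fusion --------------------------------------------------------
    def fuse(self, eye_vectors, pos_vectors=None) -> Tensor:
        """Fuse (B, 6, d) eye and position features into (B, fused_dim)."""
        eye = as_tensor(eye_vectors)
        v = self.config.variant
        if v == "none":
            return self._flatten(eye)
        if v == "self" and not self.config.multimodal:
            e = self._tokens(eye)
            return self._flatten(self.cross_block(e, e))
        if pos_vectors is None:
            raise ValueError(f"variant {v!r} requires position vectors")
        pos = as_tensor(pos_vectors)
        if eye.shape != pos.shape:
            raise ValueError(
                f"fuse: eye {eye.shape} and position {pos.shape} must align")
        if v == "self":  # multimodal: self-attention over joint tokens
            joint = nn.concat([self._tokens(eye), self._tokens(pos)], axis=2)
            return self._flatten(self.self_only(joint))
        if v == "concat":
            return nn.concat([self._flatten(eye), self._flatten(pos)], axis=1)
        if v == "cross":
            return self._flatten(self.cross_block(self._tokens(eye),
                                                  self._tokens(pos)))
        summed = eye * self.w_e + pos * self.w_p
        if v == "weighted_sum":
            return self._flatten(summed)
        # weighted_sum_self
        return self._flatten(self.self_only(self._tokens(summed)))

    def classify(self, fused) -> Tensor:
        """Case-level fused vector -> 6-class logits."""
        return self.classifier(fused)

    def forward(self, eye_vectors, pos_vectors=None) -> Tensor:
        return self.classify(self.fuse(eye_vectors, pos_vectors))


def fuse_case(module: FusionModule, eye_vectors: np.ndarray,
              pos_vectors: np.ndarray | None = None) -> np.ndarray:
    """Fuse one case's six aligned (eye, position) vector pairs."""
    eye = np.asarray(eye_vectors)[None]
    pos = None if pos_vectors is None else np.asarray(pos_vectors)[None]
    return module.fuse(eye, pos).data[0]


def classify_probabilities(module: FusionModule, fused: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for a case-level fused vector."""
    logits = module.classify(np.asarray(fused)[None])
    return nn.softmax(logits, axis=-1).data[0]
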