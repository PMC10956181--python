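"""End-to-end classifier: backbone + position autoencoder + fusion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import BackboneConfig, EyeMovementBackbone, prepare_clips
from .fusion import AttentionConfig, FusionModule
from .headpos import PositionDecoder, PositionEncoder

N_CLASSES = 6


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fusion: AttentionConfig = field(default_factory=AttentionConfig)

    def __post_init__(self):
        if self.backbone.d != self.fusion.d:
            raise ValueError(
                f"backbone d={self.backbone.d} must equal fusion d={self.fusion.d} "
                "(length-aligned feature vectors)")

    @property
    def multimodal(self) -> bool:
        return self.fusion.multimodal


class BPPVModel(nn.Module):
    """Six-position eye-movement + head-position classifier.

    The backbone is shared across the six positions; the position encoder
    and decoder exist only in multimodal configurations.  The decoder is
    kept during joint training so its reconstruction error can act as the
    loss penalty.
    """

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.backbone = EyeMovementBackbone(config.backbone, seed=seed)
        if config.multimodal:
            enc_rng = np.random.default_rng(seed + 1)
            self.encoder = PositionEncoder(d=config.fusion.d, rng=enc_rng)
            self.decoder = PositionDecoder(d=config.fusion.d, rng=enc_rng)
        else:
            self.encoder = None
            self.decoder = None
        self.fusion = FusionModule(config.fusion, N_CLASSES, seed=seed + 2)

    def load_pretrained_encoder(self, encoder: PositionEncoder,
                                decoder: PositionDecoder) -> None:
        if self.encoder is None:
            raise ValueError("unimodal model has no position encoder")
        self.encoder.load_state_dict(encoder.state_dict())
        self.decoder.load_state_dict(decoder.state_dict())

    def eye_features(self, clips: np.ndarray) -> nn.Tensor:
        """(B, 6, T, H, W) uint8/float clips -> (B, 6, d) feature vectors."""
        b, p = clips.shape[:2]
        x = prepare_clips(clips.reshape(b * p, *clips.shape[2:]))
        feats = self.backbone.features(x)
        return feats.reshape(b, p, self.config.backbone.d)

    def position_features(self, positions: np.ndarray) -> nn.Tensor:
        """(B, 6, 2) normalised position vectors -> (B, 6, d) features."""
        b, p, _ = positions.shape
        x = positions.reshape(b * p, 2).astype(nn.DEFAULT_DTYPE)
        return self.encoder(x).reshape(b, p, self.config.fusion.d)

    def forward(self, clips: np.ndarray, positions: np.ndarray | None = None) -> nn.Tensor:
        eye = self.eye_features(clips)
        pos = None
        if self.config.multimodal:
            if positions is None:
                raise ValueError("multimodal model requires position vectors")
            pos = self.position_features(positions)
        return self.fusion(eye, pos)

    def predict(self, clips: np.ndarray, positions: np.ndarray | None = None) -> np.ndarray:
        """Argmax class indices for a batch of cases."""
        return self.forward(clips, positions).data.argmax(axis=1)
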