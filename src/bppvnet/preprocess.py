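"""Clinical-protocol preprocessing: variable-length segments -> fixed input.

Pipeline per case: drop segments observed for less than 10 s, keep the six
longest surviving positions, truncate or zero-pad each to the standard
48 s observation window (1200 frames at 25 fps), subsample one frame in
four (300 frames per clip), and assemble the six clips (1800 frames
total) with their normalised head-position vectors.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .simulate import FPS, RawSegment, SyntheticCase

MIN_DURATION_S = 10.0
WINDOW_S = 48.0
WINDOW_FRAMES = int(WINDOW_S * FPS)        # 1200
SUBSAMPLE_STRIDE = 4
CLIP_FRAMES = WINDOW_FRAMES // SUBSAMPLE_STRIDE  # 300
N_POSITIONS = 6
TOTAL_FRAMES = N_POSITIONS * CLIP_FRAMES   # 1800

#: Chair angles assigned to all-black dummy segments.
NULL_POSITION = (0.0, 0.0)


@dataclass
class StandardizedInput:
    """Model-ready case: 6 aligned 300-frame clips + 6 position vectors."""

    clips: np.ndarray      # (6, 300, H, W) uint8
    positions: np.ndarray  # (6, 2) float, angles / 360
    pad_mask: np.ndarray   # (6,) int, count of zero-padded frames per clip
    case_id: str = ""
    label: str = ""

    def __post_init__(self):
        if self.clips.shape[:2] != (N_POSITIONS, CLIP_FRAMES):
            raise ValueError(
                f"clips must be ({N_POSITIONS}, {CLIP_FRAMES}, H, W), "
                f"got {self.clips.shape}")
        if self.positions.shape != (N_POSITIONS, 2):
            raise ValueError(f"positions must be (6, 2), got {self.positions.shape}")

    @property
    def total_frames(self) -> int:
        return self.clips.shape[0] * self.clips.shape[1]


def filter_segments(segments: list[RawSegment]) -> list[RawSegment]:
    """Drop segments shorter than 10 s (the >= 10 s boundary survives)."""
    return [s for s in segments if s.duration_s >= MIN_DURATION_S]


def select_positions(segments: list[RawSegment], k: int = N_POSITIONS,
                     case_id: str = "?") -> tuple[list[RawSegment], list[bool]]:
    """Keep the k longest segments, re-ordered by protocol position.

    Ties in duration are broken by protocol order.  If fewer than k
    segments survive, all-black dummy segments at the null position are
    appended; the returned boolean list flags dummies.

    Raises ValueError when no segment survives.
    """
    if not segments:
        raise ValueError(f"case {case_id!r}: no usable segments after filtering")
    order = sorted(range(len(segments)),
                   key=lambda i: (-segments[i].duration_s, i))
    chosen = sorted(order[:k])  # back to original protocol order
    selected = [segments[i] for i in chosen]
    dummy_flags = [False] * len(selected)
    while len(selected) < k:
        selected.append(_dummy_segment(selected[0]))
        dummy_flags.append(True)
    return selected, dummy_flags


def _dummy_segment(template: RawSegment) -> RawSegment:
    shape = (0,) + template.frames.shape[1:] if template.frames is not None else (0, 1, 1)
    return RawSegment(frames=np.zeros(shape, dtype=np.uint8),
                      main_deg=NULL_POSITION[0], aux_deg=NULL_POSITION[1],
                      duration_s=0.0, position=0)


def standardize_segment(segment: RawSegment | np.ndarray) -> tuple[np.ndarray, int]:
    """Truncate/pad one segment to 1200 frames, then keep 1 frame in 4.

    Returns (clip, n_padded): `clip` holds the 300 frames at indices
    0, 4, ..., 1196 of the first-1200-frame window; `n_padded` counts how
    many of them are appended all-zero padding frames.
    """
    frames = segment.frames if isinstance(segment, RawSegment) else np.asarray(segment)
    n = len(frames)
    kept_real = min(n, WINDOW_FRAMES)
    window = frames[:kept_real]
    if kept_real < WINDOW_FRAMES:
        if n > 0:
            pad_shape = (WINDOW_FRAMES - kept_real,) + frames.shape[1:]
        else:
            raise ValueError("standardize_segment: cannot infer frame shape "
                             "from an empty segment; use standardize_empty")
        window = np.concatenate([window, np.zeros(pad_shape, dtype=window.dtype)])
    clip = window[::SUBSAMPLE_STRIDE]
    n_padded = int(np.sum(np.arange(0, WINDOW_FRAMES, SUBSAMPLE_STRIDE) >= kept_real))
    return clip, n_padded


def standardize_empty(frame_shape: tuple[int, ...], dtype=np.uint8) -> tuple[np.ndarray, int]:
    """All-padding clip for an empty/dummy segment: 300 zero frames."""
    return np.zeros((CLIP_FRAMES,) + tuple(frame_shape), dtype=dtype), CLIP_FRAMES


def normalize_position(main_deg: float, aux_deg: float) -> np.ndarray:
    """Map (-360, 360) chair angles to the open unit square (-1, 1)^2."""
    for name, v in (("main_deg", main_deg), ("aux_deg", aux_deg)):
        if not -360.0 < v < 360.0:
            raise ValueError(f"{name} must lie in (-360, 360), got {v}")
    return np.array([main_deg / 360.0, aux_deg / 360.0], dtype=np.float64)


def assemble_input(case: SyntheticCase) -> StandardizedInput:
    """filter -> select -> standardize one case into a StandardizedInput."""
    surviving = filter_segments(case.segments)
    selected, dummy_flags = select_positions(surviving, N_POSITIONS, case.case_id)
    frame_shape = next(
        s.frames.shape[1:] for s in selected if s.frames is not None and len(s.frames))
    clips, pads, positions = [], [], []
    for seg, is_dummy in zip(selected, dummy_flags):
        if is_dummy or len(seg.frames) == 0:
            clip, n_pad = standardize_empty(frame_shape)
        else:
            clip, n_pad = standardize_segment(seg)
        clips.append(clip)
        pads.append(n_pad)
        positions.append(normalize_position(seg.main_deg, seg.aux_deg))
    return StandardizedInput(
        clips=np.stack(clips), positions=np.stack(positions),
        pad_mask=np.array(pads, dtype=np.int64),
        case_id=case.case_id, label=case.label)


# ---------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------

def save_standardized(inp: StandardizedInput, out_dir: str | os.PathLike) -> str:
    """Write clips as a compressed array archive plus a JSON sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    base = os.path.join(out_dir, inp.case_id or "case")
    np.savez_compressed(base + ".npz", clips=inp.clips)
    sidecar = {
        "case_id": inp.case_id,
        "label": inp.label,
        "positions": inp.positions.tolist(),
        "pad_mask": inp.pad_mask.tolist(),
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return base + ".npz"


def load_standardized(base_path: str) -> StandardizedInput:
    base, _ = os.path.splitext(base_path)
    clips = np.load(base + ".npz")["clips"]
    with open(base + ".json") as fh:
        meta = json.load(fh)
    return StandardizedInput(
        clips=clips, positions=np.asarray(meta["positions"]),
        pad_mask=np.asarray(meta["pad_mask"], dtype=np.int64),
        case_id=meta["case_id"], label=meta["label"])
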