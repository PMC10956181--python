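"""Synthetic positional-vertigo examination generator.

Produces per-case eye-movement video segments — one per examination head
position — with class- and position-dependent nystagmus, matching the
structure of a clinical videonystagmography dataset: six diagnostic
classes, a black background with a single rendered eye, segment durations
mostly between 10 and 50 s with a minority of short (<10 s) distractor
segments, and paired (main-axis, auxiliary-axis) chair angles per segment.

The nystagmus waveform is a sawtooth: a slow drift along the beat
direction followed by a fast reset, at a configurable beat frequency and
peak amplitude, on top of small Gaussian fixation jitter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FPS = 25
"""Protocol frame rate (frames per second)."""

LABELS = (
    "left-posterior",
    "right-posterior",
    "left-horizontal",
    "right-horizontal",
    "cupulolithiasis",
    "cured-or-asymptomatic",
)

#: Case counts per class matching the clinical cohort composition.
PAPER_CLASS_COUNTS = {
    "left-posterior": 120,
    "right-posterior": 147,
    "left-horizontal": 52,
    "right-horizontal": 81,
    "cupulolithiasis": 67,
    "cured-or-asymptomatic": 51,
}

#: Six canonical chair positions (main-axis deg, auxiliary-axis deg):
#: upright, supine, left/right lateral and two oblique hangs.
DEFAULT_PROTOCOL = (
    (0.0, 0.0),
    (90.0, 0.0),
    (-90.0, 0.0),
    (180.0, 0.0),
    (90.0, 90.0),
    (90.0, -90.0),
)

#: Extended protocol used by the dataset generator: the six canonical
#: positions plus two transitional postures that tend to be observed only
#: briefly, supplying the short-duration distractor segments.
DATASET_PROTOCOL = DEFAULT_PROTOCOL + ((45.0, 0.0), (135.0, 0.0))


@dataclass(frozen=True)
class NystagmusProfile:
    """Parameters of one position-triggered nystagmus episode."""

    latency_s: float
    duration_s: float
    direction_deg: float
    amplitude_px: float
    frequency_hz: float

    def __post_init__(self):
        if self.latency_s < 0:
            raise ValueError(f"latency_s must be >= 0, got {self.latency_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.amplitude_px < 0:
            raise ValueError(f"amplitude_px must be >= 0, got {self.amplitude_px}")
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency_hz must be > 0, got {self.frequency_hz}")

    def mirrored(self) -> "NystagmusProfile":
        """Reflect the beat direction about the vertical image axis."""
        return replace(self, direction_deg=(180.0 - self.direction_deg) % 360.0)


@dataclass(frozen=True)
class ClassSpec:
    """Diagnostic label plus its position-index -> nystagmus trigger map."""

    label: str
    triggers: dict[int, NystagmusProfile] = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; valid: {LABELS}")
        if self.label == "cured-or-asymptomatic" and self.triggers:
            raise ValueError("cured-or-asymptomatic must have an empty trigger map")
        if self.label != "cured-or-asymptomatic" and not self.triggers:
            raise ValueError(f"label {self.label!r} must trigger in >= 1 position")


def _default_class_specs() -> dict[str, ClassSpec]:
    # Trigger positions and directions are a simulator convention chosen so
    # that any two non-cured classes differ in active-position set or beat
    # direction; left/right pairs differ only by the mirrored direction.
    posterior = NystagmusProfile(latency_s=2.0, duration_s=30.0,
                                 direction_deg=60.0, amplitude_px=0.40,
                                 frequency_hz=3.0)
    horizontal = NystagmusProfile(latency_s=1.0, duration_s=42.0,
                                  direction_deg=0.0, amplitude_px=0.40,
                                  frequency_hz=4.0)
    cupulo = NystagmusProfile(latency_s=0.5, duration_s=70.0,
                              direction_deg=90.0, amplitude_px=0.35,
                              frequency_hz=1.5)
    return {
        "left-posterior": ClassSpec("left-posterior",
                                    {2: posterior, 5: posterior}),
        "right-posterior": ClassSpec("right-posterior",
                                     {2: posterior.mirrored(),
                                      5: posterior.mirrored()}),
        "left-horizontal": ClassSpec("left-horizontal",
                                     {3: horizontal, 4: horizontal}),
        "right-horizontal": ClassSpec("right-horizontal",
                                      {3: horizontal.mirrored(),
                                       4: horizontal.mirrored()}),
        "cupulolithiasis": ClassSpec("cupulolithiasis",
                                     {1: cupulo, 2: cupulo, 4: cupulo, 6: cupulo}),
        "cured-or-asymptomatic": ClassSpec("cured-or-asymptomatic", {}),
    }


DEFAULT_CLASS_SPECS = _default_class_specs()

# NOTE: amplitude_px in the default specs above is expressed as a FRACTION
# of the eye radius; SimulatorConfig.resolve_profile scales it to pixels so
# the same spec works at any frame size while keeping the pupil inside the
# eye disc.


@dataclass(frozen=True)
class SimulatorConfig:
    """Rendering and sampling configuration of the generator."""

    frame_size: tuple[int, int] = (64, 64)
    channels: int = 1
    fps: int = FPS
    jitter_sigma_px: float = 0.5
    angle_jitter_deg: float = 5.0     # per-case chair-angle placement error
    eye_radius_frac: float = 0.42     # eye disc radius / min(frame dims)
    pupil_radius_frac: float = 0.35   # pupil radius / eye radius
    eye_intensity: int = 190
    pupil_intensity: int = 40
    # duration mixture: (weight, low_s, high_s)
    duration_mixture: tuple[tuple[float, float, float], ...] = (
        (0.70, 10.0, 50.0),
        (0.20, 3.0, 10.0),
        (0.10, 50.0, 70.0),
    )
    min_long_segments: int = 6        # guaranteed segments of >= 10 s per case
    extra_positions_short: bool = True  # positions beyond 6 are brief
                                        # transitional observations (< 10 s)

    def __post_init__(self):
        h, w = self.frame_size
        if h <= 0 or w <= 0:
            raise ValueError(f"frame_size must be positive, got {self.frame_size}")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 (grayscale) or 3 (RGB)")
        if abs(sum(w for w, _, _ in self.duration_mixture) - 1.0) > 1e-9:
            raise ValueError("duration mixture weights must sum to 1")

    @property
    def eye_radius_px(self) -> float:
        return self.eye_radius_frac * min(self.frame_size)

    def resolve_profile(self, profile: NystagmusProfile) -> NystagmusProfile:
        """Scale a fractional-amplitude profile to pixels for this config."""
        amp = profile.amplitude_px * self.eye_radius_px
        max_amp = self.eye_radius_px * (1.0 - self.pupil_radius_frac) - 1.0
        return replace(profile, amplitude_px=min(amp, max_amp))


@dataclass
class RawSegment:
    """One head position's eye-movement clip with its chair angles."""

    frames: np.ndarray          # (T, H, W) or (T, H, W, 3) uint8
    main_deg: float
    aux_deg: float
    duration_s: float
    position: int = 0           # 1-based protocol position index

    def __post_init__(self):
        expected = int(np.floor(self.duration_s * FPS))
        if self.frames is not None and len(self.frames) != expected:
            raise ValueError(
                f"segment at position {self.position}: {len(self.frames)} frames "
                f"!= floor({self.duration_s} * {FPS}) = {expected}"
            )


@dataclass
class SyntheticCase:
    case_id: str
    label: str
    segments: list[RawSegment]
    seed: int


# ---------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------

def sawtooth_wave(t: np.ndarray, frequency_hz: float, reset_frac: float = 0.1) -> np.ndarray:
    """Unit sawtooth in [0, 1]: slow linear rise then fast linear reset.

    `reset_frac` is the fraction of each period spent on the fast phase.
    """
    phase = (t * frequency_hz) % 1.0
    rise = phase / (1.0 - reset_frac)
    fall = (1.0 - phase) / reset_frac
    return np.minimum(rise, fall)


def simulate_pupil_trajectory(
    profile: NystagmusProfile | None,
    duration_s: float,
    fps: float = FPS,
    seed: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
    jitter_sigma_px: float = 0.5,
) -> np.ndarray:
    """Simulate pupil-centre positions for one segment.

    Returns an array of shape (floor(duration_s * fps), 2) of (x, y) pixel
    offsets relative to `center`.  Outside the active nystagmus window
    (before onset latency, after latency + episode duration, or when
    `profile` is None) the pupil only jitters around the centre.  Inside
    it, a sawtooth excursion of peak `amplitude_px` along `direction_deg`
    is added; the active window is silently truncated at segment end.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    n = int(np.floor(duration_s * fps))
    rng = np.random.default_rng(seed)
    xy = np.zeros((n, 2), dtype=np.float64)
    if jitter_sigma_px > 0:
        xy += rng.normal(0.0, jitter_sigma_px, size=(n, 2))
    if profile is not None and profile.amplitude_px > 0:
        t = np.arange(n) / fps
        active = (t >= profile.latency_s) & (t < profile.latency_s + profile.duration_s)
        if active.any():
            tw = t[active] - profile.latency_s
            excursion = profile.amplitude_px * sawtooth_wave(tw, profile.frequency_hz)
            ang = np.deg2rad(profile.direction_deg)
            # image convention: +x right, +y down; direction measured CCW
            xy[active, 0] += excursion * np.cos(ang)
            xy[active, 1] -= excursion * np.sin(ang)
    return xy + np.asarray(center, dtype=np.float64)


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

def render_eye_frame(
    pupil_center: tuple[float, float],
    frame_size: tuple[int, int] = (64, 64),
    eye_radius: float | None = None,
    pupil_radius: float | None = None,
    channels: int = 1,
    eye_intensity: int = 190,
    pupil_intensity: int = 40,
) -> np.ndarray:
    """Render one frame: black background, bright eye disc, dark pupil disc.

    The eye disc is centred in the frame; `pupil_center` is in absolute
    pixel coordinates (x, y).  Deterministic given its inputs.
    """
    h, w = frame_size
    px, py = pupil_center
    if not (0 <= px < w and 0 <= py < h):
        raise ValueError(
            f"pupil_center ({px:.1f}, {py:.1f}) outside frame {w}x{h}")
    if eye_radius is None:
        eye_radius = 0.42 * min(h, w)
    if pupil_radius is None:
        pupil_radius = 0.35 * eye_radius
    frames = render_eye_frames(np.asarray([[px, py]], dtype=np.float64),
                               frame_size, eye_radius, pupil_radius,
                               channels, eye_intensity, pupil_intensity)
    return frames[0]


def render_eye_frames(
    pupil_centers: np.ndarray,
    frame_size: tuple[int, int],
    eye_radius: float,
    pupil_radius: float,
    channels: int = 1,
    eye_intensity: int = 190,
    pupil_intensity: int = 40,
) -> np.ndarray:
    """Vectorised renderer: (T, 2) pupil centres -> (T, H, W[, 3]) uint8."""
    h, w = frame_size
    t = len(pupil_centers)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    eye_mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= eye_radius ** 2
    out = np.zeros((t, h, w), dtype=np.uint8)
    out[:, eye_mask] = eye_intensity
    px = pupil_centers[:, 0][:, None, None]
    py = pupil_centers[:, 1][:, None, None]
    pupil_mask = (xx[None] - px) ** 2 + (yy[None] - py) ** 2 <= pupil_radius ** 2
    pupil_mask &= eye_mask[None]  # pupil never paints outside the eye
    out[pupil_mask] = pupil_intensity
    if channels == 3:
        out = np.repeat(out[..., None], 3, axis=-1)
    return out


# ---------------------------------------------------------------------
# cases
# ---------------------------------------------------------------------

def sample_durations(
    n_positions: int,
    rng: np.random.Generator,
    config: SimulatorConfig = SimulatorConfig(),
) -> np.ndarray:
    """Draw per-position observation durations from the configured mixture.

    Guarantees at least `config.min_long_segments` draws of >= 10 s
    (capped at n_positions) by resampling the shortest offenders from the
    long component.  With ``config.extra_positions_short`` the positions
    beyond the sixth are brief transitional observations drawn from
    Uniform(3, 10) instead of the mixture.
    """
    weights = np.array([wgt for wgt, _, _ in config.duration_mixture])
    comps = rng.choice(len(weights), size=n_positions, p=weights)
    lows = np.array([lo for _, lo, _ in config.duration_mixture])
    highs = np.array([hi for _, _, hi in config.duration_mixture])
    durations = rng.uniform(lows[comps], highs[comps])
    need = min(config.min_long_segments, n_positions)
    if config.extra_positions_short and n_positions > 6:
        durations[6:] = rng.uniform(3.0, 10.0, size=n_positions - 6)
        # the six diagnostic positions then carry the long observations
        short = np.flatnonzero(durations[:need] < 10.0)
        durations[short] = rng.uniform(10.0, 50.0, size=len(short))
        return durations
    short = np.flatnonzero(durations < 10.0)
    deficit = need - (n_positions - len(short))
    if deficit > 0:
        bump = rng.permutation(short)[:deficit]
        durations[bump] = rng.uniform(10.0, 50.0, size=deficit)
    return durations


def generate_case(
    label: str,
    protocol: tuple[tuple[float, float], ...] = DATASET_PROTOCOL,
    seed: int = 0,
    config: SimulatorConfig = SimulatorConfig(),
    class_specs: dict[str, ClassSpec] | None = None,
    case_id: str | None = None,
    render: bool = True,
) -> SyntheticCase:
    """Generate one synthetic case: one segment per protocol position.

    Nystagmus is rendered only in the positions named by the label's
    trigger map.  With ``render=False`` segments carry ``frames=None``
    (durations and angles only), for cheap statistical checks.
    """
    if len(protocol) < 6:
        raise ValueError(f"protocol must have >= 6 positions, got {len(protocol)}")
    specs = class_specs or DEFAULT_CLASS_SPECS
    if label not in specs:
        raise ValueError(f"unknown label {label!r}; valid: {sorted(specs)}")
    spec = specs[label]
    rng = np.random.default_rng(seed)
    h, w = config.frame_size
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    eye_r = config.eye_radius_px
    pupil_r = config.pupil_radius_frac * eye_r

    durations = sample_durations(len(protocol), rng, config)
    angles = [(_jitter_angle(m, rng, config.angle_jitter_deg),
               _jitter_angle(a, rng, config.angle_jitter_deg))
              for m, a in protocol]
    segments: list[RawSegment] = []
    for idx, ((main, aux), dur) in enumerate(zip(angles, durations), start=1):
        profile = spec.triggers.get(idx)
        if profile is not None:
            profile = config.resolve_profile(profile)
        traj_seed = int(rng.integers(0, 2**31 - 1))
        if render:
            traj = simulate_pupil_trajectory(
                profile, dur, config.fps, traj_seed, center,
                config.jitter_sigma_px)
            # clamp so jitter can never push the pupil against the frame edge
            traj[:, 0] = np.clip(traj[:, 0], pupil_r, w - 1 - pupil_r)
            traj[:, 1] = np.clip(traj[:, 1], pupil_r, h - 1 - pupil_r)
            frames = render_eye_frames(traj, config.frame_size, eye_r, pupil_r,
                                       config.channels, config.eye_intensity,
                                       config.pupil_intensity)
        else:
            frames = None
        segments.append(RawSegment(frames=frames, main_deg=main, aux_deg=aux,
                                   duration_s=dur, position=idx))
    return SyntheticCase(case_id=case_id or f"{label}-{seed:08d}",
                         label=label, segments=segments, seed=seed)


def _jitter_angle(deg: float, rng: np.random.Generator, jitter: float) -> float:
    """Add chair placement error, keeping the angle inside (-360, 360) and
    clear of the odd multiples of 90 deg where the gaze transform's tangent
    term is singular."""
    if jitter > 0:
        deg = deg + rng.uniform(-jitter, jitter)
    deg = float(np.clip(deg, -359.5, 359.5))
    rem = (deg - 90.0) % 180.0
    dist = min(rem, 180.0 - rem)
    if dist < 0.5:  # nudge away from the tan singularity
        deg += 0.5 if rem < 90.0 else -0.5
    return deg


def generate_dataset(
    n_per_class: dict[str, int] | str,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
    config: SimulatorConfig = SimulatorConfig(),
    protocol: tuple[tuple[float, float], ...] = DATASET_PROTOCOL,
    write_frames: bool = True,
) -> pd.DataFrame:
    """Generate a labelled dataset and return its manifest.

    `n_per_class` maps label -> case count, or is the preset name
    ``"paper"`` for the clinical cohort composition (518 cases).  When
    `out_dir` is given, per-segment frames are written as PNG directories
    (unless ``write_frames=False``) and the manifest as ``manifest.csv``.
    One manifest row per segment: case_id, label, position, main_deg,
    aux_deg, duration_s, path.
    """
    if isinstance(n_per_class, str):
        if n_per_class != "paper":
            raise ValueError(f"unknown preset {n_per_class!r}")
        n_per_class = dict(PAPER_CLASS_COUNTS)
    unknown = set(n_per_class) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels in n_per_class: {sorted(unknown)}")

    root = np.random.default_rng(seed)
    rows = []
    cases: list[SyntheticCase] = []
    for label in LABELS:
        for i in range(n_per_class.get(label, 0)):
            case_seed = int(root.integers(0, 2**31 - 1))
            case = generate_case(label, protocol, case_seed, config,
                                 case_id=f"{label}-{i:04d}",
                                 render=write_frames and out_dir is not None)
            cases.append(case)
            for seg in case.segments:
                path = ""
                if out_dir is not None and write_frames:
                    path = os.path.join(case.case_id, f"pos{seg.position}")
                    _write_png_dir(os.path.join(out_dir, path), seg.frames)
                rows.append({
                    "case_id": case.case_id, "label": label,
                    "position": seg.position, "main_deg": seg.main_deg,
                    "aux_deg": seg.aux_deg, "duration_s": seg.duration_s,
                    "path": path,
                })
    manifest = pd.DataFrame(
        rows, columns=["case_id", "label", "position", "main_deg", "aux_deg",
                       "duration_s", "path"])
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def _write_png_dir(path: str, frames: np.ndarray) -> None:
    import imageio.v3 as iio

    try:
        os.makedirs(path, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(os.path.join(path, f"{i:05d}.png"), frame)
    except OSError as exc:  # surface path and cause
        raise OSError(f"failed writing frames under {path!r}: {exc}") from exc


def load_segment_frames(dataset_dir: str, rel_path: str) -> np.ndarray:
    """Read back a PNG frame directory written by `generate_dataset`."""
    import imageio.v3 as iio

    seg_dir = os.path.join(dataset_dir, rel_path)
    names = sorted(f for f in os.listdir(seg_dir) if f.endswith(".png"))
    if not names:
        raise FileNotFoundError(f"no PNG frames under {seg_dir!r}")
    return np.stack([iio.imread(os.path.join(seg_dir, n)) for n in names])
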