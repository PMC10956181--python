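"""Simulator tests: trajectories, rendering, cases, datasets."""

import numpy as np
import pytest

from bppvnet.simulate import (
    DATASET_PROTOCOL,
    DEFAULT_CLASS_SPECS,
    DEFAULT_PROTOCOL,
    FPS,
    LABELS,
    PAPER_CLASS_COUNTS,
    ClassSpec,
    NystagmusProfile,
    SimulatorConfig,
    generate_case,
    generate_dataset,
    render_eye_frame,
    sample_durations,
    simulate_pupil_trajectory,
)


def profile(**kw):
    base = dict(latency_s=0.0, duration_s=10.0, direction_deg=0.0,
                amplitude_px=3.0, frequency_hz=2.0)
    base.update(kw)
    return NystagmusProfile(**base)


class TestTrajectory:
    def test_zero_amplitude_is_jitter_only(self):
        p = profile(amplitude_px=0.0)
        traj = simulate_pupil_trajectory(p, 4.0, seed=3, jitter_sigma_px=0.0)
        assert np.allclose(traj, 0.0)

    def test_latency_beyond_segment_means_no_active_window(self):
        p = profile(latency_s=60.0)
        active = simulate_pupil_trajectory(p, 48.0, seed=5, jitter_sigma_px=0.4)
        quiet = simulate_pupil_trajectory(None, 48.0, seed=5, jitter_sigma_px=0.4)
        assert np.array_equal(active, quiet)

    def test_frame_count(self):
        traj = simulate_pupil_trajectory(None, 12.34, fps=25, seed=0)
        assert len(traj) == int(np.floor(12.34 * 25))

    def test_sawtooth_beat_count_matches_frequency(self):
        # oracle: each sawtooth period produces exactly one fast reset,
        # i.e. one +/- sign change of the sampled displacement derivative
        p = profile(frequency_hz=2.0, amplitude_px=10.0)
        traj = simulate_pupil_trajectory(p, 10.0, fps=25, seed=0,
                                         jitter_sigma_px=0.0)
        x = traj[:, 0]
        dx = np.diff(x)
        resets = np.sum((dx[:-1] > 0) & (dx[1:] < 0))
        assert abs(resets - 2.0 * 10.0) <= 1

    def test_invalid_duration_and_fps_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_pupil_trajectory(None, 0.0)
        with pytest.raises(ValueError, match="fps"):
            simulate_pupil_trajectory(None, 1.0, fps=-1)

    def test_negative_latency_rejected(self):
        with pytest.raises(ValueError, match="latency"):
            profile(latency_s=-1.0)

    def test_determinism(self):
        p = profile()
        a = simulate_pupil_trajectory(p, 5.0, seed=11)
        b = simulate_pupil_trajectory(p, 5.0, seed=11)
        assert np.array_equal(a, b)


class TestRenderer:
    def test_background_exactly_zero(self):
        frame = render_eye_frame((20.0, 20.0), (41, 41), eye_radius=10)
        yy, xx = np.mgrid[0:41, 0:41]
        outside = (xx - 20.0) ** 2 + (yy - 20.0) ** 2 > 10 ** 2
        assert np.all(frame[outside] == 0)
        assert frame.dtype == np.uint8

    def test_deterministic(self):
        a = render_eye_frame((8.2, 7.9), (16, 16))
        b = render_eye_frame((8.2, 7.9), (16, 16))
        assert np.array_equal(a, b)

    def test_pupil_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_eye_frame((99.0, 5.0), (16, 16))

    def test_mean_intensity_conserved_under_small_shift(self):
        # area conservation: moving the pupil inside the eye disc keeps
        # the rendered disc areas (hence mean intensity) nearly unchanged
        center = render_eye_frame((20.0, 20.0), (41, 41), eye_radius=15)
        shifted = render_eye_frame((21.0, 20.0), (41, 41), eye_radius=15)
        assert abs(center.mean() - shifted.mean()) <= 0.01 * center.mean()

    def test_rgb_channels(self):
        frame = render_eye_frame((8.0, 8.0), (16, 16), channels=3)
        assert frame.shape == (16, 16, 3)
        assert np.array_equal(frame[..., 0], frame[..., 1])


class TestClassSpecs:
    def test_cured_label_has_empty_triggers(self):
        assert DEFAULT_CLASS_SPECS["cured-or-asymptomatic"].triggers == {}
        with pytest.raises(ValueError, match="empty trigger"):
            ClassSpec("cured-or-asymptomatic", {1: profile()})

    def test_non_cured_labels_trigger_somewhere(self):
        for label in LABELS:
            if label != "cured-or-asymptomatic":
                assert DEFAULT_CLASS_SPECS[label].triggers
        with pytest.raises(ValueError, match="trigger"):
            ClassSpec("left-posterior", {})

    def test_left_right_pairs_are_mirrored(self):
        for left, right in [("left-posterior", "right-posterior"),
                            ("left-horizontal", "right-horizontal")]:
            lt = DEFAULT_CLASS_SPECS[left].triggers
            rt = DEFAULT_CLASS_SPECS[right].triggers
            assert set(lt) == set(rt)
            for pos in lt:
                assert rt[pos].direction_deg == pytest.approx(
                    (180.0 - lt[pos].direction_deg) % 360.0)
                assert rt[pos].amplitude_px == lt[pos].amplitude_px

    def test_class_separability_by_construction(self):
        # any two distinct non-cured labels differ in trigger positions
        # or in beat direction at a shared position
        specs = {l: DEFAULT_CLASS_SPECS[l] for l in LABELS
                 if l != "cured-or-asymptomatic"}
        for a in specs:
            for b in specs:
                if a >= b:
                    continue
                ta, tb = specs[a].triggers, specs[b].triggers
                if set(ta) != set(tb):
                    continue
                assert any(ta[p].direction_deg != tb[p].direction_deg
                           for p in ta), (a, b)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            ClassSpec("anterior-canal", {})


class TestGenerateCase:
    def test_one_segment_per_position(self, tiny_sim_config):
        case = generate_case("cupulolithiasis", seed=1, config=tiny_sim_config)
        assert len(case.segments) == len(DATASET_PROTOCOL)
        assert [s.position for s in case.segments] == list(
            range(1, len(DATASET_PROTOCOL) + 1))

    def test_determinism(self, tiny_sim_config):
        a = generate_case("left-horizontal", seed=9, config=tiny_sim_config)
        b = generate_case("left-horizontal", seed=9, config=tiny_sim_config)
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.frames, sb.frames)
            assert sa.duration_s == sb.duration_s

    def test_cured_case_is_static_without_jitter(self, tiny_sim_config):
        case = generate_case("cured-or-asymptomatic", seed=2,
                             config=tiny_sim_config)
        for seg in case.segments:
            assert np.all(seg.frames == seg.frames[0])

    def test_triggered_positions_move(self, tiny_sim_config):
        spec = DEFAULT_CLASS_SPECS["left-posterior"]
        case = generate_case("left-posterior", seed=2, config=tiny_sim_config)
        for seg in case.segments:
            moves = bool(np.any(seg.frames != seg.frames[0]))
            assert moves == (seg.position in spec.triggers)

    def test_left_right_trajectories_mirror(self):
        # reflect-and-compare oracle on the deterministic trajectory level
        lt = DEFAULT_CLASS_SPECS["left-posterior"].triggers[2]
        rt = DEFAULT_CLASS_SPECS["right-posterior"].triggers[2]
        a = simulate_pupil_trajectory(lt, 20.0, seed=4, jitter_sigma_px=0.0)
        b = simulate_pupil_trajectory(rt, 20.0, seed=4, jitter_sigma_px=0.0)
        assert np.allclose(a[:, 0], -b[:, 0], atol=1e-9)  # x mirrored
        assert np.allclose(a[:, 1], b[:, 1], atol=1e-9)   # y identical

    def test_at_least_six_long_segments(self, tiny_sim_config):
        for seed in range(10):
            case = generate_case("right-horizontal", seed=seed,
                                 config=tiny_sim_config)
            assert sum(s.duration_s >= 10.0 for s in case.segments) >= 6

    def test_unknown_label_rejected(self, tiny_sim_config):
        with pytest.raises(ValueError, match="unknown label"):
            generate_case("meniere", config=tiny_sim_config)

    def test_short_protocol_rejected(self, tiny_sim_config):
        with pytest.raises(ValueError, match=">= 6"):
            generate_case("left-posterior", protocol=DEFAULT_PROTOCOL[:4],
                          config=tiny_sim_config)

    def test_frames_are_valid_images(self, rendered_case):
        for seg in rendered_case.segments:
            assert seg.frames.dtype == np.uint8
            assert seg.frames.min() >= 0 and seg.frames.max() <= 255


class TestDataset:
    def test_manifest_counts(self, tmp_path, tiny_sim_config):
        manifest = generate_dataset({l: 1 for l in LABELS}, seed=0,
                                    out_dir=str(tmp_path),
                                    config=tiny_sim_config,
                                    write_frames=False)
        assert manifest["case_id"].nunique() == 6
        per_case = manifest.groupby("case_id").size()
        assert (per_case >= 6).all()
        assert (tmp_path / "manifest.csv").exists()
        cols = list(manifest.columns)
        assert cols == ["case_id", "label", "position", "main_deg",
                        "aux_deg", "duration_s", "path"]

    def test_png_roundtrip(self, tmp_path):
        from bppvnet.simulate import load_segment_frames

        config = SimulatorConfig(
            frame_size=(8, 8),
            duration_mixture=((1.0, 10.0, 11.0),))
        manifest = generate_dataset({"left-posterior": 1}, seed=3,
                                    out_dir=str(tmp_path), config=config)
        row = manifest.iloc[0]
        frames = load_segment_frames(str(tmp_path), row.path)
        assert len(frames) == int(np.floor(row.duration_s * FPS))

    def test_paper_preset_case_count(self):
        manifest = generate_dataset("paper", seed=0, write_frames=False)
        assert manifest["case_id"].nunique() == 518
        counts = manifest.drop_duplicates("case_id")["label"].value_counts()
        assert counts.to_dict() == PAPER_CLASS_COUNTS

    def test_duration_distribution_shape(self):
        # pooled over 100 cases the 10-50 s band dominates the >= 50 s band
        manifest = generate_dataset({l: 17 for l in LABELS[:6]}, seed=1,
                                    write_frames=False)
        d = manifest["duration_s"].to_numpy()
        frac_mid = np.mean((d >= 10) & (d < 50))
        frac_long = np.mean(d >= 50)
        assert frac_mid > frac_long
        assert np.mean(d < 10) > 0  # short distractors present

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            generate_dataset("clinic")


class TestSampleDurations:
    def test_long_guarantee(self, rng):
        cfg = SimulatorConfig()
        for _ in range(20):
            d = sample_durations(8, rng, cfg)
            assert np.sum(d >= 10.0) >= 6

    def test_extra_positions_short(self, rng):
        cfg = SimulatorConfig()
        d = sample_durations(8, rng, cfg)
        assert np.all(d[6:] < 10.0)
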