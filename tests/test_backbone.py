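"""Backbone tests: frame differences, short/long-term modules, features."""

import numpy as np
import pytest

from bppvnet import nn
from bppvnet.backbone import (
    BackboneConfig,
    EyeMovementBackbone,
    LongTermModule,
    ShortTermModule,
    extract_eye_features,
    frame_difference,
    frame_difference_all,
    frame_difference_batch,
    prepare_clips,
    set_kernel_mode,
    split_halves,
)
from bppvnet.nn.tensor import Tensor

CFG = BackboneConfig(kernel_mode="big", d=8, base_channels=4, stage_blocks=1,
                     stages=2, frame_size=(8, 8))


def small_clip(rng, t=20, h=8, w=8):
    return rng.uniform(0, 1, size=(1, t, 1, h, w)).astype(np.float32)


class TestFrameDifference:
    def test_constant_video_gives_zero_maps(self):
        stack = np.full((10, 1, 4, 4), 7.0)
        d = frame_difference(stack, 5)
        assert d.shape == (4, 1, 4, 4)
        assert np.allclose(d, 0.0)

    def test_linear_ramp_closed_form(self):
        j = np.arange(12, dtype=float).reshape(1, 3, 4)
        stack = np.stack([i * j for i in range(10)])
        d = frame_difference(stack, 5)
        for m, k in zip(d, (-2, -1, 1, 2)):
            assert np.allclose(m, k * j)

    def test_boundary_clamped(self):
        stack = np.stack([i * np.ones((1, 2, 2)) for i in range(6)])
        d0 = frame_difference(stack, 0)
        # frames -2, -1 clamp to frame 0 -> zero difference
        assert np.allclose(d0[0], 0.0)
        assert np.allclose(d0[1], 0.0)
        assert np.allclose(d0[2], 1.0)

    def test_time_reversal_symmetry(self, rng):
        # brute force: with D_k = I_{i+k} - I_i, reversing time maps the
        # offset-k map onto the offset-(-k) map of the forward stack
        stack = rng.standard_normal((11, 2, 3, 3))
        i = 5
        fwd = frame_difference(stack, i)
        rev = frame_difference(stack[::-1], len(stack) - 1 - i)
        assert np.allclose(rev, fwd[::-1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="T >= 5"):
            frame_difference(np.zeros((4, 1, 2, 2)), 1)
        with pytest.raises(ValueError, match="T >= 5"):
            frame_difference_all(np.zeros((3, 1, 2, 2)))

    def test_batch_matches_single(self, rng):
        stacks = rng.standard_normal((2, 8, 1, 4, 4))
        batch = frame_difference_batch(stacks)
        for b in range(2):
            assert np.allclose(batch[b], frame_difference_all(stacks[b]))


class TestShortTerm:
    def test_output_shapes(self, rng):
        st = ShortTermModule(CFG, np.random.default_rng(0))
        x = small_clip(rng)
        o1, o2 = st.branches(x)
        assert o1.shape == (1, 5, 4, 4, 4)   # T/4, C, H/2, W/2
        assert o2.shape == (1, 5, 4, 8, 8)
        out = st(x)
        assert out.shape == (1, 5, 4, 4, 4)

    def test_temporal_downsampling_factor_for_300_frames(self, rng):
        st = ShortTermModule(CFG, np.random.default_rng(0))
        x = rng.uniform(0, 1, size=(1, 300, 1, 8, 8)).astype(np.float32)
        o1, _ = st.branches(x)
        assert o1.shape[1] == 75

    def test_indivisible_temporal_length_rejected(self, rng):
        st = ShortTermModule(CFG, np.random.default_rng(0))
        with pytest.raises(ValueError, match="divisible by 4"):
            st(rng.uniform(size=(1, 10, 1, 8, 8)).astype(np.float32))

    def test_constant_video_with_zeroed_motion_branch(self, rng):
        # zero the whole motion branch: output reduces to the upsampled
        # appearance ResLayer path
        st = ShortTermModule(CFG, np.random.default_rng(0))
        for mod in [st.conv3d_diff] + st.res_motion:
            for p in mod.parameters():
                p.data[:] = 0.0
        x = np.full((1, 8, 1, 8, 8), 0.5, dtype=np.float32)
        out = st(x).data
        o1, o2 = st.branches(x)
        from bppvnet.backbone import _apply_blocks, _upsample_to
        ref = _upsample_to(_apply_blocks(st.res_app, o2), o1).data
        assert np.allclose(out, ref, atol=1e-6)

    def test_linearity_of_appearance_branch(self, rng):
        # bias-free, activation-stubbed: doubling input doubles O2
        st = ShortTermModule(CFG, np.random.default_rng(0))
        st.use_activation = False
        st.conv3d_diff.bias.data[:] = 0.0
        st.conv3d_app.bias.data[:] = 0.0
        x = small_clip(rng, t=8)
        _, o2a = st.branches(x)
        _, o2b = st.branches(2.0 * x)
        assert np.allclose(o2b.data, 2.0 * o2a.data, rtol=1e-4, atol=1e-5)


class TestSplit:
    def test_even_halves_disjoint(self):
        s1, s2 = split_halves(10)
        assert (s1.start, s1.stop) == (0, 5)
        assert (s2.start, s2.stop) == (5, 10)

    def test_odd_halves_overlap_one(self):
        s1, s2 = split_halves(9)
        assert (s1.stop - s1.start) == (s2.stop - s2.start) == 5
        overlap = set(range(s1.start, s1.stop)) & set(range(s2.start, s2.stop))
        assert overlap == {4}

    def test_split_channels_reduces_by_r(self, rng):
        lt = LongTermModule(4, CFG, np.random.default_rng(0))
        f = Tensor(rng.standard_normal((1, 10, 4, 4, 4)).astype(np.float32))
        f1, f2 = lt.split_channels(f)
        assert f1.shape == f2.shape == (1, 5, 2, 4, 4)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            LongTermModule(5, CFG, np.random.default_rng(0))


class TestGate:
    def _gate_inputs(self, rng, t=6, c=2, h=4, w=4):
        return (Tensor(rng.standard_normal((1, t, c, h, w)).astype(np.float32)),
                Tensor(rng.standard_normal((1, t, c, h, w)).astype(np.float32)))

    def test_values_strictly_in_unit_interval(self, rng):
        lt = LongTermModule(4, CFG, np.random.default_rng(0))
        f1, f2 = self._gate_inputs(rng)
        m = lt.gate(f1, f2).data
        assert np.all((m > 0) & (m < 1))

    def test_zero_weights_give_half(self, rng):
        lt = LongTermModule(4, CFG, np.random.default_rng(0))
        for p in lt.parameters():
            p.data[:] = 0.0
        f1, f2 = self._gate_inputs(rng)
        m = lt.gate(f1, f2).data
        assert np.allclose(m, 0.5)

    def test_same_padding_preserves_spatial_shape(self, rng):
        lt = LongTermModule(4, CFG, np.random.default_rng(0))
        f1, f2 = self._gate_inputs(rng, h=8, w=8)
        assert lt.gate(f1, f2).shape == f1.shape

    def test_shape_mismatch_named(self, rng):
        lt = LongTermModule(4, CFG, np.random.default_rng(0))
        f1, _ = self._gate_inputs(rng)
        f2 = Tensor(np.zeros((1, 6, 2, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="split halves"):
            lt.gate(f1, f2)


class TestLongTerm:
    def _module_and_input(self, rng, t=10):
        lt = LongTermModule(4, CFG, np.random.default_rng(0))
        f = Tensor(rng.standard_normal((1, t, 4, 4, 4)).astype(np.float32))
        return lt, f

    def test_stubbed_zero_gate_gives_identity(self, rng, monkeypatch):
        lt, f = self._module_and_input(rng)
        monkeypatch.setattr(lt, "gate",
                            lambda a, b: nn.as_tensor(np.zeros_like(a.data)))
        assert np.allclose(lt(f).data, f.data)

    def test_stubbed_unit_gate_doubles(self, rng, monkeypatch):
        lt, f = self._module_and_input(rng)
        monkeypatch.setattr(lt, "gate",
                            lambda a, b: nn.as_tensor(np.ones_like(a.data)))
        assert np.allclose(lt(f).data, 2.0 * f.data, rtol=1e-6)

    def test_symmetrisation_makes_order_irrelevant(self, rng):
        # asymmetric stub: average over both argument orders is symmetric
        lt, f = self._module_and_input(rng)
        f1, f2 = lt.split_channels(f)
        a = (lt.gate(f1, f2).data + lt.gate(f2, f1).data) / 2
        b = (lt.gate(f2, f1).data + lt.gate(f1, f2).data) / 2
        assert np.allclose(a, b)

    def test_gate_boundedness_implies_output_bound(self, rng):
        lt, f = self._module_and_input(rng)
        out = lt(f).data
        assert np.all(np.abs(out) <= 2.0 * np.abs(f.data) + 1e-5)


class TestKernelMode:
    def test_big_has_more_parameters(self):
        big = EyeMovementBackbone(CFG, seed=0)
        base = EyeMovementBackbone(set_kernel_mode(CFG, "baseline"), seed=0)
        assert big.n_parameters() > base.n_parameters()

    def test_both_modes_output_d(self, rng):
        x = small_clip(rng)
        for mode in ("big", "baseline"):
            bb = EyeMovementBackbone(set_kernel_mode(CFG, mode), seed=0)
            assert bb.features(x).shape == (1, CFG.d)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            set_kernel_mode(CFG, "huge")
        with pytest.raises(ValueError, match="kernel_mode"):
            BackboneConfig(kernel_mode="huge")

    def test_df_receptive_field_is_kernel_size(self):
        # impulse-response support of the DF convolution: 13 (big) vs 3
        for mode, expected in (("big", 13), ("baseline", 3)):
            cfg = set_kernel_mode(CFG, mode)
            lt = LongTermModule(4, cfg, np.random.default_rng(0))
            k = lt.conv_df.weight.data
            assert k.shape[-2:] == (expected, expected)
            impulse = np.zeros((1, 1, 2, 31, 31), dtype=np.float32)
            impulse[0, 0, 0, 15, 15] = 1.0
            lt.conv_df.weight.data[:] = 1.0
            lt.conv_df.bias.data[:] = 0.0
            resp = lt.conv_df(nn.as_tensor(impulse)).data[0, 0, 0]
            # threshold above float32 FFT noise
            rows = np.flatnonzero(np.abs(resp).sum(axis=1) > 1e-3)
            assert rows[-1] - rows[0] + 1 == expected


class TestFeatureExtraction:
    def test_deterministic(self, rng):
        bb = EyeMovementBackbone(CFG, seed=0)
        clip = (rng.uniform(0, 255, size=(20, 8, 8))).astype(np.uint8)
        a = extract_eye_features(bb, clip)
        b = extract_eye_features(bb, clip)
        assert np.array_equal(a, b)
        assert a.shape == (CFG.d,)

    def test_null_embedding_for_all_zero_clips(self):
        bb = EyeMovementBackbone(CFG, seed=0)
        a = extract_eye_features(bb, np.zeros((20, 8, 8), dtype=np.uint8))
        b = extract_eye_features(bb, np.zeros((20, 8, 8), dtype=np.uint8))
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_weight_sharing_equivariance(self, rng):
        # permuting the six positions permutes the six feature vectors
        bb = EyeMovementBackbone(CFG, seed=0)
        clips = rng.uniform(0, 1, size=(6, 20, 1, 8, 8)).astype(np.float32)
        feats = bb.features(clips).data
        perm = rng.permutation(6)
        feats_perm = bb.features(clips[perm]).data
        assert np.allclose(feats_perm, feats[perm], atol=1e-5)

    def test_prepare_clips_shapes_and_range(self, rng):
        gray = rng.integers(0, 255, size=(2, 10, 8, 8), dtype=np.uint8)
        out = prepare_clips(gray)
        assert out.shape == (2, 10, 1, 8, 8)
        assert out.max() <= 1.0
        rgb = rng.integers(0, 255, size=(2, 10, 8, 8, 3), dtype=np.uint8)
        assert prepare_clips(rgb).shape == (2, 10, 3, 8, 8)
        with pytest.raises(ValueError):
            prepare_clips(rng.integers(0, 255, size=(10, 8, 8)))
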