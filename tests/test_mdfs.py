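"""Multi-scale difference stem: stream construction, fusion, stem modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulseforge import nn
from pulseforge.mdfs import (DiffStack, MDFSStem, StemConfig, fuse_and_activate,
                             fusion_weights, multi_scale_difference)


def _clip(d=8, c=3, h=8, w=8, seed=0):
    return np.random.default_rng(seed).random((d, c, h, w)).astype(np.float32)


class TestMultiScaleDifference:
    def test_identical_frames_give_zero_differences(self):
        x = np.broadcast_to(_clip(d=1), (6, 3, 8, 8)).copy()
        stack = multi_scale_difference(x, (1, 2, 3))
        for delta in stack.streams[1:]:
            np.testing.assert_array_equal(delta, 0.0)

    def test_scalar_ramp_constant_difference(self):
        # X[t] = t/8 everywhere -> Delta_2[t] = 2/8 for t >= 2, 0 before
        x = (np.arange(6, dtype=np.float32) / 8.0)[:, None, None, None]
        x = np.broadcast_to(x, (6, 1, 4, 4)).copy()
        stack = multi_scale_difference(x, (1, 2, 3))
        d2 = stack.streams[2]
        np.testing.assert_array_equal(d2[:2], 0.0)
        np.testing.assert_allclose(d2[2:], 2.0 / 8.0, atol=1e-7)

    def test_matches_bruteforce_subtraction(self):
        x = _clip(d=10, seed=42)
        stack = multi_scale_difference(x, (1, 2, 3))
        for s, delta in zip((1, 2, 3), stack.streams[1:]):
            brute = np.zeros_like(x)
            for t in range(s, 10):
                brute[t] = x[t] - x[t - s]
            np.testing.assert_array_equal(delta, brute)

    def test_original_stream_unmodified(self):
        x = _clip()
        stack = multi_scale_difference(x)
        np.testing.assert_array_equal(stack.streams[0], x)

    def test_scale_not_below_clip_length(self):
        with pytest.raises(ValueError):
            multi_scale_difference(_clip(d=3), (1, 2, 3))

    @given(st.integers(4, 16), st.integers(1, 3))
    @settings(max_examples=20, deadline=None)
    def test_zero_padding_property(self, d, s):
        x = np.random.default_rng(d * 7 + s).random((d, 1, 4, 4)).astype(np.float32)
        stack = multi_scale_difference(x, (s,))
        np.testing.assert_array_equal(stack.streams[1][:s], 0.0)

    def test_static_offset_invariance(self):
        """Adding a constant to every frame leaves all difference streams unchanged."""
        x = _clip() * 0.5
        a = multi_scale_difference(x, (1, 2, 3))
        b = multi_scale_difference(x + 0.25, (1, 2, 3))
        for da, db in zip(a.streams[1:], b.streams[1:]):
            np.testing.assert_allclose(da, db, atol=1e-6)

    def test_batched_input_differences_along_frame_axis(self):
        x = np.random.default_rng(0).random((2, 6, 3, 4, 4)).astype(np.float32)
        stack = multi_scale_difference(x, (1,))
        np.testing.assert_allclose(stack.streams[1][:, 1:],
                                   x[:, 1:] - x[:, :-1], atol=1e-7)

    def test_mismatched_stream_shapes_rejected(self):
        with pytest.raises(ValueError):
            DiffStack(streams=(np.zeros((2, 1, 4, 4)), np.zeros((3, 1, 4, 4))),
                      scales=(1,))


class TestFusionWeights:
    def test_zero_logits_uniform(self):
        w = fusion_weights(np.zeros(4)).data
        np.testing.assert_allclose(w, 0.25, atol=1e-7)

    def test_ln2_closed_form(self):
        w = fusion_weights(np.array([np.log(2.0), 0.0, 0.0, 0.0])).data
        np.testing.assert_allclose(w, [0.4, 0.2, 0.2, 0.2], atol=1e-6)

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_normalized_and_finite_even_at_large_logits(self, logits):
        """Max-subtracted softmax never overflows, sums to 1, stays in [0, 1];
        strictly positive whenever the logit spread is within float32 range."""
        logits = np.array(logits)
        w = fusion_weights(logits).data
        assert np.isfinite(w).all()
        assert abs(w.sum() - 1.0) < 1e-5
        assert (w >= 0).all() and (w <= 1.0 + 1e-6).all()
        if logits.max() - logits.min() < 80:   # exp stays in float32 range
            assert (w > 0).all()

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            fusion_weights(np.array([np.inf, 0, 0, 0]))


class TestFuseAndActivate:
    def test_one_hot_weights_select_single_stream(self, rng):
        feats = [nn.Tensor(rng.standard_normal((2, 4, 4))) for _ in range(4)]
        w = fusion_weights(np.array([60.0, 0.0, 0.0, 0.0]))  # ~one-hot
        out = fuse_and_activate(feats, w)
        np.testing.assert_allclose(out.data, np.maximum(feats[0].data, 0), atol=1e-5)

    def test_equal_streams_identity(self, rng):
        f = nn.Tensor(rng.standard_normal((3, 4, 4)))
        out = fuse_and_activate([f, f, f, f], fusion_weights(rng.standard_normal(4)))
        np.testing.assert_allclose(out.data, np.maximum(f.data, 0), atol=1e-6)

    def test_equal_weights_match_average_oracle(self, rng):
        feats = [rng.standard_normal((2, 3, 3)).astype(np.float32) for _ in range(4)]
        out = fuse_and_activate([nn.Tensor(f) for f in feats],
                                fusion_weights(np.zeros(4)))
        oracle = np.maximum(np.mean(feats, axis=0), 0.0)
        np.testing.assert_allclose(out.data, oracle, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_and_activate([nn.Tensor(np.zeros((2, 2))),
                               nn.Tensor(np.zeros((3, 2)))],
                              fusion_weights(np.zeros(2)))


class TestBranchesAndDropout:
    def test_branch_output_shape(self, rng):
        from pulseforge.mdfs import _Branch
        br = _Branch(3, 8, rng=rng)
        out = br(nn.Tensor(rng.random((5, 3, 32, 32)).astype(np.float32)))
        assert out.shape == (5, 8, 8, 8)

    def test_zero_input_zero_bias_branch_outputs_zero(self, rng):
        from pulseforge.mdfs import _Branch
        br = _Branch(3, 4, rng=rng)
        br.eval()   # avoid division by zero batch variance in train mode
        out = br(nn.Tensor(np.zeros((2, 3, 16, 16), np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_dropout_eval_identity(self, rng):
        drop = nn.Dropout2d(0.5, rng=rng)
        drop.eval()
        x = nn.Tensor(rng.random((2, 8, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(drop(x).data, x.data)

    def test_dropout_zero_rate_identity(self, rng):
        drop = nn.Dropout2d(0.0, rng=rng)
        x = nn.Tensor(rng.random((2, 8, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(drop(x).data, x.data)

    def test_dropout_channel_semantics_and_scaling(self):
        drop = nn.Dropout2d(0.5, rng=np.random.default_rng(0))
        x = nn.Tensor(np.ones((1, 8, 4, 4), np.float32))
        out = drop(x).data
        for ch in range(8):
            channel = out[0, ch]
            assert (channel == 0).all() or np.allclose(channel, 2.0)
        assert (out == 0).any() and (out == 2.0).any()

    def test_dropout_invalid_rate(self, rng):
        with pytest.raises(ValueError):
            nn.Dropout2d(1.0, rng=rng)


class TestStemForward:
    def _stem(self, mode="full", seed=0, dropout=0.0, **kw):
        cfg = StemConfig(c_mid=8, dropout=dropout, mode=mode, **kw)
        return MDFSStem(3, cfg, rng=np.random.default_rng(seed))

    def test_output_shape_and_nonnegativity(self, rng):
        stem = self._stem()
        x = rng.random((2, 6, 3, 16, 16)).astype(np.float32)
        out = stem(x)
        assert out.shape == (12, 8, 4, 4)
        assert (out.data >= 0).all()

    def test_original_only_ignores_temporal_structure(self, rng):
        """original_only depends only on per-frame content, not frame order."""
        stem = self._stem(mode="original_only")
        stem.eval()
        x = rng.random((1, 6, 3, 16, 16)).astype(np.float32)
        out1 = stem(x).data
        perm = x[:, ::-1].copy()
        out2 = stem(perm).data
        np.testing.assert_allclose(out1[::-1], out2, atol=1e-6)

    def test_fixed_uniform_equals_full_with_zero_logits(self, rng):
        full = self._stem(mode="full", seed=3)
        full.eval()
        fixed = self._stem(mode="fixed", seed=3,
                           fixed_weights=(0.25, 0.25, 0.25, 0.25))
        fixed.eval()
        x = rng.random((1, 5, 3, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(full(x).data, fixed(x).data, atol=1e-6)

    def test_fixed_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            StemConfig(mode="fixed", fixed_weights=(0.5, 0.5, 0.5, 0.5))

    def test_indivisible_spatial_dims_rejected(self, rng):
        stem = self._stem()
        with pytest.raises(ValueError):
            stem(rng.random((1, 5, 3, 15, 15)).astype(np.float32))

    def test_eval_mode_deterministic(self, rng):
        stem = self._stem(dropout=0.3)
        stem.eval()
        x = rng.random((1, 5, 3, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(stem(x).data, stem(x).data)
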