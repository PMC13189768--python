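"""SCOPE refinement block: attention submodules, gating, variants, CBAM."""

import numpy as np
import pytest

from pulseforge import nn
from pulseforge.scope import CBAMBlock, SCOPE, ScopeConfig, VARIANTS


def _scope(variant="full", c=8, r=4, seed=0, **kw):
    cfg = ScopeConfig(reduction=r, variant=variant, **kw)
    return SCOPE(c, cfg, rng=np.random.default_rng(seed))


def _x(b=2, c=8, h=4, w=4, seed=1):
    return nn.Tensor(np.random.default_rng(seed)
                     .standard_normal((b, c, h, w)).astype(np.float32))


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestChannelAttention:
    def test_zero_mlp_gives_half_attention(self):
        sc = _scope()
        _zero_params(sc.channel_mlp)
        x = _x()
        a, xc = sc.channel_attention(x)
        np.testing.assert_allclose(a.data, 0.5, atol=1e-7)
        np.testing.assert_allclose(xc.data, 0.5 * x.data, atol=1e-6)

    def test_attention_in_open_unit_interval(self):
        a, _ = _scope().channel_attention(_x())
        assert (a.data > 0).all() and (a.data < 1).all()

    def test_per_location_mlp_matches_matrix_oracle(self):
        """Attention at each spatial location equals a hand-rolled two-layer
        MLP on that location's channel vector, and differs across locations."""
        sc = _scope(c=6, r=2, seed=9)
        x = _x(b=1, c=6, h=1, w=2, seed=5)
        a, _ = sc.channel_attention(x)
        w1, b1 = sc.channel_mlp.fc1.weight.data, sc.channel_mlp.fc1.bias.data
        w2, b2 = sc.channel_mlp.fc2.weight.data, sc.channel_mlp.fc2.bias.data
        for loc in range(2):
            v = x.data[0, :, 0, loc]
            hid = np.maximum(v @ w1 + b1, 0)
            expect = 1.0 / (1.0 + np.exp(-(hid @ w2 + b2)))
            np.testing.assert_allclose(a.data[0, :, 0, loc], expect, atol=1e-5)
        assert not np.allclose(a.data[0, :, 0, 0], a.data[0, :, 0, 1])

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError):
            _scope(c=6, r=4)


class TestSpatialAttention:
    def test_nonnegative_and_shape_preserving(self):
        sc = _scope()
        sc.eval()
        x = _x()
        a, xs = sc.spatial_attention(x)
        assert (a.data >= 0).all()
        assert xs.shape == x.shape

    def test_matches_composition_oracle(self):
        """x_spa equals the explicit conv->BN->ReLU->conv->BN->ReLU chain
        applied with the same parameters, times the input."""
        from pulseforge.nn import functional as F
        sc = _scope(c=4, r=2, seed=11)
        sc.eval()
        x = _x(b=1, c=4, h=8, w=8, seed=2)
        a, xs = sc.spatial_attention(x)
        sp = sc.spatial
        h1 = F.conv2d(x, sp.conv1.weight, sp.conv1.bias, 1, 3)
        h1 = F.batch_norm_2d(h1, sp.bn1.gamma, sp.bn1.beta, sp.bn1.running_mean,
                             sp.bn1.running_var, training=False).relu()
        h2 = F.conv2d(h1, sp.conv2.weight, sp.conv2.bias, 1, 3)
        h2 = F.batch_norm_2d(h2, sp.bn2.gamma, sp.bn2.beta, sp.bn2.running_mean,
                             sp.bn2.running_var, training=False).relu()
        np.testing.assert_allclose(a.data, h2.data, atol=1e-5)
        np.testing.assert_allclose(xs.data, (x * h2).data, atol=1e-5)

    def test_optional_terminal_sigmoid_bounds_map(self):
        sc = _scope(spatial_sigmoid=True)
        sc.eval()
        a, _ = sc.spatial_attention(_x())
        assert (a.data > 0).all() and (a.data < 1).all()


class TestGate:
    def test_zero_gate_params_give_half(self):
        sc = _scope()
        _zero_params(sc.gate)
        g = sc.gate_map(_x())
        assert g.shape == (2, 8, 1, 1)
        np.testing.assert_allclose(g.data, 0.5, atol=1e-7)

    def test_saturated_negative_bias_closes_gate(self):
        sc = _scope()
        _zero_params(sc.gate)
        sc.gate.conv2.bias.data[...] = -20.0
        g = sc.gate_map(_x())
        assert (g.data < 1e-8).all()

    def test_constant_map_matches_scalar_chain_oracle(self):
        sc = _scope(c=4, r=2, seed=21)
        v = 0.7
        x = nn.Tensor(np.full((1, 4, 5, 5), v, np.float32))
        g = sc.gate_map(x).data[0, :, 0, 0]
        w1 = sc.gate.conv1.weight.data[:, :, 0, 0]
        b1 = sc.gate.conv1.bias.data
        w2 = sc.gate.conv2.weight.data[:, :, 0, 0]
        b2 = sc.gate.conv2.bias.data
        hid = np.maximum(w1 @ np.full(4, v) + b1, 0)
        expect = 1.0 / (1.0 + np.exp(-(w2 @ hid + b2)))
        np.testing.assert_allclose(g, expect, atol=1e-5)


class TestForwardVariants:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_shape_preserved(self, variant):
        sc = _scope(variant=variant)
        sc.eval()
        x = _x()
        assert sc(x).shape == x.shape

    def test_closed_gate_yields_identity(self):
        sc = _scope()
        sc.eval()
        _zero_params(sc.gate)
        sc.gate.conv2.bias.data[...] = -40.0
        x = _x()
        np.testing.assert_allclose(sc(x).data, x.data, atol=1e-5)

    def test_no_gate_with_zero_refinement_is_identity(self):
        sc = _scope(variant="no_gate")
        sc.eval()
        _zero_params(sc.spatial)   # conv weights zero -> a_spa = ReLU(BN(0)) = 0
        x = _x()
        np.testing.assert_allclose(sc(x).data, x.data, atol=1e-6)

    def test_full_variant_equals_staged_composition(self):
        sc = _scope(seed=33)
        sc.eval()
        x = _x(seed=7)
        _, x_chan = sc.channel_attention(x)
        _, x_spa = sc.spatial_attention(x_chan)
        g = sc.gate_map(x_spa)
        expect = (g * x_spa + x).data
        np.testing.assert_allclose(sc(x).data, expect, atol=1e-6)

    def test_residual_dominance_bound(self):
        """|out - x| is bounded by max(g) * max|x_spa| elementwise."""
        sc = _scope(seed=2)
        sc.eval()
        x = _x(seed=8)
        _, x_chan = sc.channel_attention(x)
        _, x_spa = sc.spatial_attention(x_chan)
        g = sc.gate_map(x_spa)
        diff = np.abs(sc(x).data - x.data).max()
        bound = g.data.max() * np.abs(x_spa.data).max()
        assert diff <= bound + 1e-6

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ScopeConfig(variant="bogus")

    def test_gradients_reach_all_parameter_groups(self):
        sc = _scope(seed=4)
        x = _x(seed=3)
        (sc(x) ** 2.0).sum().backward()
        for name, p in sc.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
        # at least one nonzero gradient per submodule
        for sub in (sc.channel_mlp, sc.spatial, sc.gate):
            assert any(np.abs(p.grad).max() > 0 for p in sub.parameters())

    def test_variant_parameter_counts(self):
        full = _scope().num_parameters()
        chan = _scope(variant="channel_only").num_parameters()
        spat = _scope(variant="spatial_only").num_parameters()
        nogate = _scope(variant="no_gate").num_parameters()
        c, r = 8, 4
        mlp = c * (c // r) + c // r + (c // r) * c + c          # two linears
        convs = 2 * (c * c * 49 + c) + 2 * 2 * c                # 7x7 convs + BN
        gate = c * (c // r) + c // r + (c // r) * c + c          # two 1x1 convs
        assert full == mlp + convs + gate
        assert chan == mlp + gate
        assert spat == convs + gate
        assert nogate == mlp + convs


class TestCBAM:
    def test_shape_and_residual(self):
        blk = CBAMBlock(8, r=4, rng=np.random.default_rng(0))
        x = _x()
        out = blk(x)
        assert out.shape == x.shape

    def test_zeroed_block_reduces_to_residual_half(self):
        """With all parameters zero the channel and spatial sigmoids are 0.5,
        so the output is x * 0.25 + x."""
        blk = CBAMBlock(8, r=4, rng=np.random.default_rng(0))
        _zero_params(blk)
        x = _x()
        np.testing.assert_allclose(blk(x).data, 0.25 * x.data + x.data, atol=1e-6)

    def test_scope_cbam_variant_dispatches(self):
        sc = _scope(variant="cbam")
        x = _x()
        assert sc(x).shape == x.shape
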