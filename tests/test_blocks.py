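"""Attention-block behaviour: hand-evaluated gate values, shape contracts,
boundedness, and the TLA composition oracle."""

import numpy as np
import pytest

from tla_unet.autograd import Tensor, concat
from tla_unet.blocks import (AttentionGate, ChannelAttention, SqueezeExcitation,
                             TLABlock, apply_spatial_coefficients,
                             attention_gate, channel_attention,
                             squeeze_excitation, tla_block)

SIGMA_2 = 1.0 / (1.0 + np.exp(-2.0))          # sigmoid at pre-activation 2


def make_rng():
    return np.random.default_rng(7)


def identity_gate() -> AttentionGate:
    """1-channel gate with identity projections and zero biases."""
    gate = AttentionGate(1, 1, make_rng())
    for conv in (gate.theta_x, gate.theta_z, gate.phi):
        conv.weight.data[:] = 1.0
        conv.bias.data[:] = 0.0
    return gate


class TestAttentionGate:
    def test_zero_skip_features_give_zero_output(self, rng):
        gate = AttentionGate(4, 4, make_rng())
        out = attention_gate(np.zeros((4, 8, 8)), rng.normal(size=(4, 8, 8)), gate)
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_weights_reproduce_hand_value(self):
        out = attention_gate(np.ones((1, 2, 2)), np.ones((1, 2, 2)), identity_gate())
        np.testing.assert_allclose(out, SIGMA_2, atol=1e-4)
        assert abs(SIGMA_2 - 0.88080) < 1e-4

    def test_coarser_gating_signal_is_upsampled(self, rng):
        gate = AttentionGate(64, 64, make_rng())
        out = attention_gate(rng.normal(size=(64, 28, 28)),
                             rng.normal(size=(64, 14, 14)), gate)
        assert out.shape == (64, 28, 28)

    def test_non_integer_ratio_rejected(self, rng):
        gate = AttentionGate(2, 2, make_rng())
        with pytest.raises(ValueError, match="integer-ratio"):
            attention_gate(rng.normal(size=(2, 9, 9)),
                           rng.normal(size=(2, 6, 6)), gate)

    def test_gating_never_amplifies(self, rng):
        gate = AttentionGate(3, 5, make_rng())
        x = rng.normal(size=(3, 8, 8))
        out = attention_gate(x, rng.normal(size=(5, 4, 4)), gate)
        assert (np.abs(out) <= np.abs(x) + 1e-12).all()


class TestChannelAttention:
    def test_zero_input_gives_zero_output(self):
        ca = ChannelAttention(4, make_rng(), reduction=2)
        np.testing.assert_array_equal(channel_attention(np.zeros((4, 5, 5)), ca), 0.0)

    def test_identity_mlp_gives_sigmoid_of_twice_value(self):
        ca = ChannelAttention(1, make_rng(), reduction=1)
        for fc in (ca.fc1, ca.fc2):
            fc.weight.data[:] = 1.0
            fc.bias.data[:] = 0.0
        v = 0.7
        f = np.full((1, 3, 3), v)
        expected = f / (1.0 + np.exp(-2 * v))
        np.testing.assert_allclose(channel_attention(f, ca), expected, atol=1e-6)

    def test_output_bounded_by_input(self, rng):
        ca = ChannelAttention(8, make_rng(), reduction=4)
        f = rng.normal(size=(8, 6, 6))
        out = channel_attention(f, ca)
        assert (np.abs(out) <= np.abs(f) + 1e-12).all()

    def test_rejects_nonfinite_input(self):
        ca = ChannelAttention(2, make_rng(), reduction=1)
        bad = np.full((2, 3, 3), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            channel_attention(bad, ca)

    def test_rejects_non_dividing_reduction(self):
        with pytest.raises(ValueError, match="reduction"):
            ChannelAttention(6, make_rng(), reduction=4)


class TestSqueezeExcitation:
    def test_zero_input_with_zero_bias_gives_zeros(self):
        se = SqueezeExcitation(2, make_rng(), reduction=1)
        se.fc1.bias.data[:] = 0.0
        se.fc2.bias.data[:] = 0.0
        np.testing.assert_array_equal(squeeze_excitation(np.zeros((2, 4, 4)), se), 0.0)

    def test_identity_weights_reproduce_hand_value(self):
        se = SqueezeExcitation(1, make_rng(), reduction=1)
        for fc in (se.fc1, se.fc2):
            fc.weight.data[:] = 1.0
            fc.bias.data[:] = 0.0
        c = 1.3
        expected = c / (1.0 + np.exp(-c))      # c * sigmoid(ReLU(c))
        np.testing.assert_allclose(
            squeeze_excitation(np.full((1, 2, 2), c), se), expected, atol=1e-6)

    def test_shape_preserved(self, rng):
        se = SqueezeExcitation(128, make_rng(), reduction=16)
        out = squeeze_excitation(rng.normal(size=(128, 14, 14)), se)
        assert out.shape == (128, 14, 14)

    def test_rejects_non_dividing_reduction(self):
        with pytest.raises(ValueError, match="reduction"):
            SqueezeExcitation(10, make_rng(), reduction=4)


class TestApplySpatialCoefficients:
    def test_ones_map_is_identity(self, rng):
        fz = rng.normal(size=(3, 4, 4))
        np.testing.assert_array_equal(
            apply_spatial_coefficients(fz, np.ones((1, 4, 4))), fz)

    def test_zeros_map_annihilates(self, rng):
        fz = rng.normal(size=(3, 4, 4))
        np.testing.assert_array_equal(
            apply_spatial_coefficients(fz, np.zeros((1, 4, 4))), 0.0)

    def test_matches_per_channel_loop_oracle(self, rng):
        fz = rng.normal(size=(3, 4, 4))
        ws = rng.random(size=(1, 4, 4))
        out = apply_spatial_coefficients(fz, ws)
        expected = np.empty_like(fz)
        for c in range(3):
            for i in range(4):
                for j in range(4):
                    expected[c, i, j] = fz[c, i, j] * ws[0, i, j]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_spatial_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="match"):
            apply_spatial_coefficients(rng.normal(size=(3, 4, 4)),
                                       np.ones((1, 5, 5)))


class TestTLABlock:
    def make_block(self):
        return TLABlock(6, 8, 6, make_rng(), reduction=2)

    def test_shape_contract_with_coarse_inputs(self, rng):
        block = TLABlock(64, 128, 64, make_rng())
        block.eval()
        out = tla_block(rng.normal(size=(64, 56, 56)),
                        rng.normal(size=(128, 28, 28)),
                        rng.random(size=(1, 14, 14)), block)
        assert out.shape == (64, 56, 56)

    def test_equals_manual_chain_of_sub_operations(self, rng):
        """Composition oracle: AG -> concat(up) -> CA -> double conv -> Ws."""
        block = self.make_block()
        block.eval()
        skip = rng.normal(size=(1, 6, 8, 8))
        gating = rng.normal(size=(1, 8, 4, 4))
        ws = rng.random(size=(1, 1, 8, 8))

        out = block(Tensor(skip), Tensor(gating), Tensor(ws)).data

        gated = block.ag(Tensor(skip), Tensor(gating))
        up = Tensor(gating).bilinear_resize((8, 8))
        attended = block.ca(concat([gated, up], axis=1))
        fz = block.conv(attended)
        manual = (fz * Tensor(ws)).data
        np.testing.assert_array_equal(out, manual)

    def test_degenerate_attention_reduces_to_plain_double_conv(self, rng):
        """With Ws = 1 and channel attention forced fully open, the block is
        the plain decoder double conv on the gated concatenation."""
        block = self.make_block()
        block.eval()
        block.ca.fc1.weight.data[:] = 0.0
        block.ca.fc1.bias.data[:] = 0.0
        block.ca.fc2.weight.data[:] = 0.0
        block.ca.fc2.bias.data[:] = 40.0       # sigmoid saturates to 1.0 exactly
        skip = rng.normal(size=(1, 6, 8, 8))
        gating = rng.normal(size=(1, 8, 4, 4))
        ws = np.ones((1, 1, 8, 8))

        out = block(Tensor(skip), Tensor(gating), Tensor(ws)).data

        gated = block.ag(Tensor(skip), Tensor(gating))
        up = Tensor(gating).bilinear_resize((8, 8))
        plain = block.conv(concat([gated, up], axis=1)).data
        np.testing.assert_array_equal(out, plain)

    def test_deterministic_in_eval_mode(self, rng):
        block = self.make_block()
        block.eval()
        args = (rng.normal(size=(6, 8, 8)), rng.normal(size=(8, 4, 4)),
                rng.random(size=(1, 8, 8)))
        np.testing.assert_array_equal(tla_block(*args, block),
                                      tla_block(*args, block))
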