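"""Hand-evaluated loss values and the algebraic identities of the compound
objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tla_unet.autograd import Tensor
from tla_unet.losses import (compound_loss, cross_entropy_loss,
                             deep_supervision_loss, dice_loss, one_hot)


def uniform_pair(c: int = 4, n: int = 10):
    """One-hot truth vs the uniform prediction 1/C."""
    rng = np.random.default_rng(0)
    labels = rng.integers(0, c, size=n)
    u = np.zeros((c, n))
    u[labels, np.arange(n)] = 1.0
    y = np.full((c, n), 1.0 / c)
    return u, y


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        u = np.eye(3)
        assert cross_entropy_loss(u, u) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_equals_log_c(self):
        u, y = uniform_pair(c=4)
        assert cross_entropy_loss(u, y) == pytest.approx(np.log(4), abs=1e-4)

    def test_epsilon_clamp_keeps_loss_finite(self):
        u = np.eye(2)
        y = np.array([[0.0, 1.0], [1.0, 0.0]])    # zero mass on true class
        val = cross_entropy_loss(u, y)
        assert np.isfinite(val)
        assert val == pytest.approx(-np.log(1e-7), rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy_loss(np.eye(2), np.eye(3))


class TestDice:
    def test_perfect_one_hot_is_zero(self):
        u, _ = uniform_pair(c=3, n=8)
        assert dice_loss(u, u) == pytest.approx(0.0, abs=1e-4)

    def test_disjoint_hard_predictions_score_one(self):
        u = np.zeros((2, 4)); u[0] = 1.0
        y = np.zeros((2, 4)); y[1] = 1.0
        assert dice_loss(u, y) == pytest.approx(1.0, abs=1e-4)

    def test_single_class_toy_overlap(self):
        """|truth| = 4, |prediction| = 4, overlap 2 -> loss 0.5."""
        u = np.zeros((1, 10)); u[0, :4] = 1.0
        y = np.zeros((1, 10)); y[0, 2:6] = 1.0
        assert dice_loss(u, y) == pytest.approx(0.5, abs=1e-4)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        u = rng.random((3, 7)); y = rng.random((3, 7))
        assert dice_loss(u, y) == pytest.approx(dice_loss(y, u), abs=1e-12)

    def test_range_and_pixel_permutation_invariance(self):
        rng = np.random.default_rng(2)
        u, _ = uniform_pair(c=3, n=20)
        y = rng.dirichlet(np.ones(3), size=20).T
        val = dice_loss(u, y)
        assert 0.0 <= val <= 1.0 + 1e-9
        perm = rng.permutation(20)
        assert dice_loss(u[:, perm], y[:, perm]) == pytest.approx(val, abs=1e-12)
        assert cross_entropy_loss(u[:, perm], y[:, perm]) == \
            pytest.approx(cross_entropy_loss(u, y), abs=1e-12)


class TestCompound:
    def test_weight_identities(self):
        rng = np.random.default_rng(3)
        u, _ = uniform_pair(c=3, n=12)
        y = rng.dirichlet(np.ones(3), size=12).T
        assert compound_loss(u, y, 1.0, 0.0) == pytest.approx(dice_loss(u, y), abs=1e-12)
        assert compound_loss(u, y, 0.0, 1.0) == pytest.approx(
            cross_entropy_loss(u, y), abs=1e-12)
        assert compound_loss(u, y) == pytest.approx(
            0.5 * dice_loss(u, y) + 0.5 * cross_entropy_loss(u, y), abs=1e-12)

    def test_toy_composition_value(self):
        """Dice 0.5 and CE ln 4 at equal weights combine to 0.94315."""
        u_d = np.zeros((1, 10)); u_d[0, :4] = 1.0
        y_d = np.zeros((1, 10)); y_d[0, 2:6] = 1.0
        u_c, y_c = uniform_pair(c=4)
        value = compound_loss(u_d, y_d, 0.5, 0.0) + compound_loss(u_c, y_c, 0.0, 0.5)
        assert value == pytest.approx(0.94315, abs=1e-4)

    def test_negative_weights_rejected(self):
        u, y = uniform_pair()
        with pytest.raises(ValueError, match=">= 0"):
            compound_loss(u, y, -0.1, 0.5)

    def test_both_components_zero_gives_zero(self):
        u = np.eye(4)
        assert compound_loss(u, u) == pytest.approx(0.0, abs=1e-4)


class TestDeepSupervision:
    def logits_and_truth(self, m: int):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(2, 3, 4, 4))
        truth = one_hot(rng.integers(0, 3, size=(2, 4, 4)), 3)
        return [Tensor(logits) for _ in range(m)], truth

    def test_single_output_equals_compound_on_softmax(self):
        (lg,), u = self.logits_and_truth(1)
        probs = lg.softmax(axis=1).data
        assert deep_supervision_loss([lg], u) == pytest.approx(
            compound_loss(u, probs), abs=1e-12)

    def test_identical_outputs_average_to_single_value(self):
        lgs, u = self.logits_and_truth(3)
        assert deep_supervision_loss(lgs, u) == pytest.approx(
            deep_supervision_loss(lgs[:1], u), abs=1e-12)

    def test_two_outputs_average_arithmetically(self):
        rng = np.random.default_rng(5)
        a = Tensor(rng.normal(size=(1, 3, 4, 4)))
        b = Tensor(rng.normal(size=(1, 3, 4, 4)))
        u = one_hot(rng.integers(0, 3, size=(1, 4, 4)), 3)
        la = deep_supervision_loss([a], u)
        lb = deep_supervision_loss([b], u)
        assert deep_supervision_loss([a, b], u) == pytest.approx(
            (la + lb) / 2, abs=1e-12)

    def test_empty_output_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            deep_supervision_loss([], np.zeros((1, 3, 4, 4)))

    def test_spatial_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        lg = Tensor(rng.normal(size=(1, 3, 4, 4)))
        u = one_hot(rng.integers(0, 3, size=(1, 8, 8)), 3)
        with pytest.raises(ValueError, match="spatial"):
            deep_supervision_loss([lg], u)


class TestLossProperties:
    """Algebraic invariants over randomly drawn probability fields."""

    @staticmethod
    def _pair(seed, c=3, n=15):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, c, size=n)
        u = np.zeros((c, n)); u[labels, np.arange(n)] = 1.0
        y = rng.dirichlet(np.ones(c), size=n).T
        return u, y

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ranges_and_affine_compound(self, seed):
        u, y = self._pair(seed)
        d, ce = dice_loss(u, y), cross_entropy_loss(u, y)
        assert 0.0 <= d <= 1.0 + 1e-9
        assert ce >= 0.0
        for l1, l2 in [(0.5, 0.5), (1.0, 0.0), (0.2, 1.3)]:
            assert compound_loss(u, y, l1, l2) == pytest.approx(
                l1 * d + l2 * ce, abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dice_symmetry_on_probability_fields(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.dirichlet(np.ones(3), size=12).T
        y = rng.dirichlet(np.ones(3), size=12).T
        assert dice_loss(u, y) == pytest.approx(dice_loss(y, u), abs=1e-12)


def test_one_hot_round_trip_and_bounds():
    rng = np.random.default_rng(7)
    mask = rng.integers(0, 4, size=(2, 5, 5))
    u = one_hot(mask, 4)
    assert u.shape == (2, 4, 5, 5)
    np.testing.assert_array_equal(u.sum(axis=1), 1.0)
    np.testing.assert_array_equal(np.argmax(u, axis=1), mask)
    with pytest.raises(ValueError, match="exceed"):
        one_hot(mask, 3)
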