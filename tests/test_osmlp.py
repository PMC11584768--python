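"""Ordered shift MLP block: channel ordering, grouped axial shifts,
positional token MLPs and their composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

from dranet import nn
from dranet.errors import ConfigurationError, InvalidInputError
from dranet.osmlp import (ChannelOrder, OrderedShiftMLP, PositionalTokenMLP,
                          ScoreMLP, ShiftSpec, axial_group_shift,
                          compute_channel_order, inverse_order,
                          osmlp_forward, positional_token_mlp,
                          reorder_channels)

from conftest import assert_grad_matches

identity = lambda v: v


class TestChannelOrder:
    def test_constant_input_gives_identity_order(self):
        x = np.ones((3, 3, 5))
        order = compute_channel_order(x, identity)
        np.testing.assert_array_equal(order.order, np.arange(5))

    def test_per_channel_constants_sort_descending(self):
        # channels constant at (1, 5, 3): avg-pool == max-pool, scores (2, 10, 6)
        x = np.zeros((2, 2, 3))
        x[..., 0], x[..., 1], x[..., 2] = 1.0, 5.0, 3.0
        order = compute_channel_order(x, identity)
        np.testing.assert_array_equal(order.order, [1, 2, 0])
        np.testing.assert_allclose(order.scores, [2.0, 10.0, 6.0])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_order_is_permutation(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(1, 9))
        x = rng.normal(size=(3, 4, c))
        mlp = ScoreMLP(c, rng)
        order = compute_channel_order(x, mlp)
        assert sorted(order.order.tolist()) == list(range(c))

    def test_scores_sorted_descending_with_stable_ties(self):
        x = np.zeros((1, 1, 4))
        x[..., 0], x[..., 1], x[..., 2], x[..., 3] = 2.0, 7.0, 7.0, 1.0
        order = compute_channel_order(x, identity)
        np.testing.assert_array_equal(order.order, [1, 2, 0, 3])
        s = order.scores[order.order]
        assert np.all(np.diff(s) <= 0)

    def test_nonfinite_input_rejected(self):
        x = np.ones((2, 2, 3))
        x[0, 0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            compute_channel_order(x, identity)


class TestReorder:
    def test_identity_order_is_noop(self, rng):
        x = rng.normal(size=(3, 3, 4))
        out = reorder_channels(x, np.arange(4))
        np.testing.assert_array_equal(out.data, x)

    def test_inverse_recovers_input(self, rng):
        x = rng.normal(size=(3, 3, 4))
        order = np.array([2, 0, 3, 1])
        back = reorder_channels(reorder_channels(x, order), inverse_order(order))
        np.testing.assert_array_equal(back.data, x)

    def test_matches_naive_copy_oracle(self, rng):
        x = rng.normal(size=(3, 3, 4))
        order = np.array([2, 0, 3, 1])
        out = reorder_channels(x, order).data
        oracle = np.empty_like(x)
        for h in range(3):
            for w in range(3):
                for j, src in enumerate(order):
                    oracle[h, w, j] = x[h, w, src]
        np.testing.assert_array_equal(out, oracle)

    def test_preserves_channel_multiset(self, rng):
        x = rng.normal(size=(4, 4, 6))
        out = reorder_channels(x, np.array([5, 3, 1, 0, 2, 4])).data
        a = np.sort(x.reshape(-1, 6), axis=-1)
        b = np.sort(out.reshape(-1, 6), axis=-1)
        np.testing.assert_array_equal(a, b)

    def test_non_permutation_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            reorder_channels(rng.normal(size=(2, 2, 3)), np.array([0, 0, 2]))


class TestAxialGroupShift:
    def test_zero_offsets_identity(self, rng):
        x = rng.normal(size=(4, 4, 4))
        out = axial_group_shift(x, ShiftSpec(2, (0, 0), "height"))
        np.testing.assert_array_equal(out.data, x)

    def test_height_shift_worked_example(self):
        x = np.zeros((4, 1, 2))
        x[:, 0, 0] = [1, 2, 3, 4]
        x[:, 0, 1] = [10, 20, 30, 40]
        out = axial_group_shift(x, ShiftSpec(2, (1, -1), "height")).data
        np.testing.assert_array_equal(out[:, 0, 0], [0, 1, 2, 3])
        np.testing.assert_array_equal(out[:, 0, 1], [20, 30, 40, 0])

    @pytest.mark.parametrize("axis", ["height", "width"])
    def test_matches_roll_with_zero_fill_oracle(self, axis, rng):
        x = rng.normal(size=(5, 6, 6))
        spec = ShiftSpec(3, (-2, 0, 1), axis)
        out = axial_group_shift(x, spec).data
        ax = 0 if axis == "height" else 1
        oracle = np.zeros_like(x)
        for c in range(6):
            off = spec.offsets[c // 2]
            rolled = np.roll(x[..., c], off, axis=ax)
            if off > 0:
                sl = [slice(None)] * 2
                sl[ax] = slice(0, off)
                rolled[tuple(sl)] = 0
            elif off < 0:
                sl = [slice(None)] * 2
                sl[ax] = slice(off, None)
                rolled[tuple(sl)] = 0
            oracle[..., c] = rolled
        np.testing.assert_array_equal(out, oracle)

    def test_definition_as_property(self, rng):
        x = rng.normal(size=(6, 5, 4))
        spec = ShiftSpec(4, (-1, 0, 1, 2), "height")
        out = axial_group_shift(x, spec).data
        for h in range(6):
            for w in range(5):
                for c in range(4):
                    src = h - spec.offsets[c]
                    expected = x[src, w, c] if 0 <= src < 6 else 0.0
                    assert out[h, w, c] == expected

    def test_indivisible_group_count_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            axial_group_shift(rng.normal(size=(4, 4, 5)), ShiftSpec(2, (0, 1), "height"))


class TestPositionalTokenMLP:
    def test_shape_preserved(self, rng):
        block = PositionalTokenMLP(6, rng)
        x = rng.normal(size=(5, 7, 6))
        assert positional_token_mlp(x, block).shape == (5, 7, 6)

    def test_zero_input_zero_biases_gives_zero(self, rng):
        block = PositionalTokenMLP(4, rng)  # biases start at zero
        out = positional_token_mlp(np.zeros((3, 3, 4)), block)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-15)

    def test_hand_evaluated_chain_on_single_pixel(self, rng):
        block = PositionalTokenMLP(2, rng, hidden=2)
        w1 = np.array([[0.3, -0.2], [0.1, 0.4]])
        w2 = np.array([[0.5, 0.2], [-0.3, 0.6]])
        dw = np.zeros((3, 3, 2))
        dw[1, 1] = [0.7, -0.5]          # only the center tap hits a 1x1 map
        pw = np.array([[1.1, -0.4], [0.2, 0.9]])
        block.mlp.fc1.weight.data = w1
        block.mlp.fc2.weight.data = w2
        block.dw.weight.data = dw
        block.pw.weight.data = pw.reshape(1, 1, 2, 2)
        x = np.array([[[1.0, -1.0]]])

        g = lambda v: v * 0.5 * (1.0 + erf(v / np.sqrt(2.0)))
        y = g(x[0, 0] @ w1) @ w2
        y = y * dw[1, 1]
        y = g(y @ pw)
        np.testing.assert_allclose(positional_token_mlp(x, block).data[0, 0], y,
                                   rtol=1e-12)


class TestBlockForward:
    def test_shape_preserved(self, rng):
        block = OrderedShiftMLP(8, rng, groups=4)
        assert osmlp_forward(rng.normal(size=(8, 8, 8)), block).shape == (8, 8, 8)

    def test_equals_staged_composition(self, rng):
        block = OrderedShiftMLP(8, rng, groups=4)
        x = rng.normal(size=(8, 8, 8))
        s1 = compute_channel_order(x, block.score1)
        xs = reorder_channels(x, s1)
        th = axial_group_shift(xs, block.shift_h)
        t = positional_token_mlp(th, block.token_mlp)
        s2 = compute_channel_order(t, block.score2)
        ts = reorder_channels(t, s2)
        tw = axial_group_shift(ts, block.shift_w)
        manual = block.out_mlp(tw)
        np.testing.assert_allclose(osmlp_forward(x, block).data, manual.data, rtol=1e-12)

    def test_deterministic_across_calls(self, rng):
        block = OrderedShiftMLP(8, rng)
        x = rng.normal(size=(4, 4, 8))
        a = osmlp_forward(x, block).data
        b = osmlp_forward(x, block).data
        np.testing.assert_array_equal(a, b)

    def test_reduces_to_mlp_stages_with_null_shift_and_tied_orders(self, rng):
        block = OrderedShiftMLP(4, rng, groups=2, offsets=(0, 0))
        # zero the score MLPs: all scores tie, both orderings become identity
        for mlp in (block.score1, block.score2):
            mlp.fc1.weight.data[:] = 0.0
            mlp.fc2.weight.data[:] = 0.0
        x = rng.normal(size=(5, 5, 4))
        expected = block.out_mlp(block.token_mlp(nn.Tensor(x[None])))
        np.testing.assert_allclose(osmlp_forward(x, block).data, expected.data[0],
                                   rtol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        block = OrderedShiftMLP(4, rng, groups=2)
        x = rng.normal(size=(4, 4, 4))
        assert_grad_matches(
            lambda t: (osmlp_forward(t, block) ** 2.0).sum(),
            lambda a: (osmlp_forward(nn.Tensor(a), block) ** 2.0).sum().item(),
            x, rtol=1e-4)
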