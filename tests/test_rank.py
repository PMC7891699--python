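"""Rank-order coding primitives: rank transform, activation, WTA plasticity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from corticobasal.rank import (
    RankFunction,
    ROCLayer,
    rank_transform,
    select_winner,
    train_layer,
)

F = RankFunction()

finite_vectors = arrays(
    np.float64,
    st.integers(1, 30),
    elements=st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
)


class TestRankFunction:
    def test_harmonic_values(self):
        np.testing.assert_allclose(F.values(3), [1.0, 0.5, 1 / 3])

    def test_power_family_strictly_decreasing_in_unit_interval(self):
        for p in (0.5, 1.0, 2.0):
            v = RankFunction("power", p).values(12)
            assert np.all(np.diff(v) < 0)
            assert np.all((v > 0) & (v <= 1))

    def test_self_match_bound(self):
        assert F.self_match(3) == pytest.approx(1 + 0.25 + 1 / 9)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            RankFunction("exponential")
        with pytest.raises(ValueError):
            RankFunction("power", -1.0)


class TestRankTransform:
    def test_printed_example(self):
        np.testing.assert_allclose(
            rank_transform(np.array([0.9, 0.1, 0.5]), F), [1.0, 1 / 3, 0.5]
        )

    def test_constant_vector_tie_break_by_index(self):
        np.testing.assert_allclose(
            rank_transform(np.array([2.0, 2.0, 2.0]), F), [1.0, 0.5, 1 / 3]
        )

    def test_sorted_input_gives_f_in_order(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.normal(size=8))[::-1]
        np.testing.assert_allclose(rank_transform(x, F), F.values(8))

    @settings(derandomize=True)
    @given(finite_vectors)
    def test_output_is_permutation_of_f_image(self, x):
        code = rank_transform(x, F)
        np.testing.assert_allclose(np.sort(code), np.sort(F.values(len(x))))

    @settings(derandomize=True)
    @given(finite_vectors)
    def test_largest_amplitude_gets_f0(self, x):
        code = rank_transform(x, F)
        assert code[np.argmax(x)] == pytest.approx(F.values(len(x))[0])

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            rank_transform(np.array([]), F)
        with pytest.raises(ValueError):
            rank_transform(np.array([1.0, np.nan]), F)
        with pytest.raises(ValueError):
            rank_transform(np.array([1.0, np.inf]), F)


class TestActivation:
    def test_self_match_is_upper_bound(self):
        x = np.array([0.9, 0.1, 0.5])
        code = rank_transform(x, F)
        layer = ROCLayer(weights=code[None, :], alpha=np.array([0.5]), f=F)
        assert layer.activate(code)[0] == pytest.approx(F.self_match(3))

    def test_zero_weights_silent(self):
        layer = ROCLayer(weights=np.zeros((4, 3)), alpha=np.full(4, 0.5), f=F)
        assert np.all(layer.activate(rank_transform(np.array([3.0, 1.0, 2.0]), F)) == 0)

    def test_hand_dot_product(self):
        # w = [0.5, 1.0, 1/3] against the code of [0.9, 0.1, 0.5]
        layer = ROCLayer(
            weights=np.array([[0.5, 1.0, 1 / 3]]), alpha=np.array([0.5]), f=F
        )
        code = rank_transform(np.array([0.9, 0.1, 0.5]), F)
        assert layer.activate(code)[0] == pytest.approx(
            0.5 * 1.0 + 1.0 * (1 / 3) + (1 / 3) * 0.5
        )

    def test_dimension_mismatch_rejected(self):
        layer = ROCLayer.create(2, 3, F, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer.activate(np.ones(4))

    def test_self_order_maximal_over_all_permutations(self):
        """Exhaustive check (M=5): a rank-code row is maximally activated
        exactly by codes sharing its ordering (rearrangement inequality)."""
        from itertools import permutations

        base = F.values(5)
        row = base[np.array([2, 0, 4, 1, 3])]
        layer = ROCLayer(weights=row[None, :], alpha=np.array([0.5]), f=F)
        best = max(
            (float(layer.activate(base[np.array(p)])[0]), p)
            for p in permutations(range(5))
        )
        assert best[1] == (2, 0, 4, 1, 3)
        assert best[0] == pytest.approx(F.self_match(5))


class TestSelectWinner:
    def test_basic_and_tie(self):
        assert select_winner(np.array([0.1, 0.9, 0.3])) == 1
        assert select_winner(np.array([0.5, 0.5])) == 0

    @settings(derandomize=True)
    @given(arrays(np.float64, st.integers(1, 1000),
                  elements=st.floats(-1e3, 1e3, allow_nan=False)))
    def test_matches_bruteforce_argmax(self, y):
        best, idx = -np.inf, -1
        for i, v in enumerate(y):
            if v > best:
                best, idx = v, i
        assert select_winner(y) == idx

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_winner(np.array([]))


class TestUpdateWinner:
    def test_full_step_reaches_target(self):
        layer = ROCLayer(weights=np.full((2, 3), 0.2), alpha=np.array([1.0, 1.0]), f=F)
        target = rank_transform(np.array([0.3, 0.9, 0.5]), F)
        layer.update_winner(0, target)
        np.testing.assert_allclose(layer.weights[0], target)
        np.testing.assert_allclose(layer.weights[1], 0.2)  # only row b changes

    def test_geometric_contraction_constant_alpha(self):
        layer = ROCLayer(
            weights=np.full((1, 3), 0.5), alpha=np.array([0.3]), f=F,
            gamma=1.0, alpha_min=0.3,
        )
        target = rank_transform(np.array([0.9, 0.1, 0.5]), F)
        d0 = np.abs(layer.weights[0] - target).max()
        layer.update_winner(0, target)
        assert np.abs(layer.weights[0] - target).max() == pytest.approx(0.7 * d0)

    def test_fifty_presentations_converge(self):
        """Iterating w <- w + 0.3(t - w) 50 times from 0.5 lands within 1e-6
        (frozen oracle: 0.5 + (t-0.5)(1-(0.7)^50), |residual| < 1.8e-8)."""
        layer = ROCLayer(
            weights=np.full((1, 3), 0.5), alpha=np.array([0.3]), f=F,
            gamma=1.0, alpha_min=0.3,
        )
        target = rank_transform(np.array([0.9, 0.1, 0.5]), F)
        for _ in range(50):
            layer.update_winner(0, target)
        assert np.abs(layer.weights[0] - target).max() < 1e-6

    def test_alpha_decays_only_for_winner(self):
        layer = ROCLayer.create(3, 4, F, rng=np.random.default_rng(1),
                                alpha_init=0.8, gamma=0.9)
        layer.update_winner(1, F.values(4))
        assert layer.alpha[1] == pytest.approx(0.72)
        assert layer.alpha[0] == pytest.approx(0.8)

    def test_weights_stay_in_unit_interval(self):
        rng = np.random.default_rng(2)
        layer = ROCLayer.create(4, 6, F, rng=rng)
        for _ in range(200):
            x = rng.normal(size=6)
            code = rank_transform(x, F)
            b = select_winner(layer.activate(code))
            layer.update_winner(b, code)
        assert np.all((layer.weights >= 0) & (layer.weights <= 1))

    def test_invalid_winner_rejected(self):
        layer = ROCLayer.create(2, 3, F, rng=np.random.default_rng(0))
        with pytest.raises(IndexError):
            layer.update_winner(5, F.values(3))


class TestTraining:
    def test_prototype_recovery(self):
        """K ordering-distinct patterns, K <= N: each pattern claims its own
        winner and the winner rows converge to the patterns' rank codes.
        (Patterns sharing their amplitude ordering are indistinguishable to
        rank coding, so distinctness is enforced in ordering space.)"""
        from corticobasal.synth import make_prototypes

        protos = make_prototypes(10, seed=0, max_code_sim=0.8).vectors
        layer = ROCLayer.create(20, 12, F, rng=np.random.default_rng(100))
        winners = train_layer(layer, protos, periods=5)
        last = winners[-1]
        assert len(set(last.tolist())) == 10
        for i, p in enumerate(protos):
            code = rank_transform(p, F)
            assert np.abs(layer.weights[last[i]] - code).max() < 1e-3

    def test_winner_log_shape(self):
        rng = np.random.default_rng(4)
        layer = ROCLayer.create(5, 4, F, rng=rng)
        winners = train_layer(layer, rng.uniform(size=(7, 4)), periods=3)
        assert winners.shape == (3, 7)


class TestSerialization:
    def test_bit_exact_roundtrip(self, tmp_path):
        layer = ROCLayer.create(6, 5, RankFunction("power", 2.0),
                                rng=np.random.default_rng(5), name="PAC")
        layer.save(tmp_path / "layer")
        loaded = ROCLayer.load(tmp_path / "layer")
        assert np.array_equal(layer.weights, loaded.weights)
        assert np.array_equal(layer.alpha, loaded.alpha)
        assert loaded.f == layer.f
        assert loaded.name == "PAC"
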