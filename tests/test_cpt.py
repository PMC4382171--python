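"""The CPT value/weighting functions, decision weights, and choice rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affectcpt import (
    ChoiceRule,
    CPTParams,
    Lottery,
    choice_prob,
    decision_weights,
    expected_value,
    softmax_choice_prob,
    valuation,
    value_fn,
    weight_fn,
)
from conftest import random_loss_lottery


def oracle_weight(p, gamma, delta):
    return delta * p**gamma / (delta * p**gamma + (1 - p) ** gamma)


def oracle_decision_weights(outcomes, probs, gamma, delta):
    """Independent telescoping-sum implementation on ranked outcomes."""
    order = sorted(range(len(outcomes)), key=lambda i: -outcomes[i])
    outs = [outcomes[i] for i in order]
    ps = [probs[i] for i in order]
    k = len(outs)
    weights = []
    for j in range(k):
        tail = 1.0 if j == 0 else sum(ps[j:])  # complete lottery: full tail is 1
        tail_next = sum(ps[j + 1:])
        weights.append(oracle_weight(tail, gamma, delta) - oracle_weight(tail_next, gamma, delta))
    return outs, weights


class TestValueFunction:
    @pytest.mark.parametrize(
        "x, alpha, expected",
        [
            (-50, 1.0, -50.0),
            (0, 0.5, 0.0),
            (-18, 0.73, -math.exp(0.73 * math.log(18))),
        ],
    )
    def test_values(self, x, alpha, expected):
        assert value_fn(x, alpha) == pytest.approx(expected, abs=1e-9)

    def test_rejects_gains(self):
        with pytest.raises(ValueError):
            value_fn(3.0, 0.8)

    def test_convex_for_losses(self):
        xs = np.linspace(-100, -0.5, 50)
        v = value_fn(xs, 0.6)
        # convexity: second differences of v on an even grid are >= 0
        assert np.all(np.diff(v, 2) >= -1e-9)


class TestWeightFunction:
    @pytest.mark.parametrize(
        "p, gamma, delta, expected",
        [
            (0.15, 1.0, 1.0, 0.15),
            (1.0, 0.43, 2.47, 1.0),
            (0.05, 0.43, 2.47, oracle_weight(0.05, 0.43, 2.47)),
        ],
    )
    def test_values(self, p, gamma, delta, expected):
        assert weight_fn(p, gamma, delta) == pytest.approx(expected, abs=1e-9)

    def test_endpoints_exact(self):
        assert weight_fn(0.0, 0.3, 4.0) == 0.0
        assert weight_fn(1.0, 0.3, 4.0) == 1.0

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.05, 1.0), st.floats(0.1, 10.0))
    def test_strictly_increasing(self, gamma, delta):
        ps = np.linspace(0.0, 1.0, 101)
        w = weight_fn(ps, gamma, delta)
        assert np.all(np.diff(w) > 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            weight_fn(1.5, 0.5, 1.0)


class TestDecisionWeights:
    def test_identity_reduces_to_probabilities(self):
        lot = Lottery([-18, 0], [0.15, 0.85])
        pi = decision_weights(lot, 1.0, 1.0)
        # sorted order: 0 first, -18 last
        assert pi == pytest.approx([0.85, 0.15], abs=1e-12)

    def test_sure_loss(self):
        assert decision_weights(Lottery([-50], [1.0]), 0.43, 2.47) == pytest.approx([1.0])

    def test_three_branch_matches_oracle_and_sums_to_one(self):
        lot = Lottery([0, -5, -50], [0.7, 0.2, 0.1])
        pi = decision_weights(lot, 0.43, 2.47)
        _, expected = oracle_decision_weights(lot.outcomes, lot.probs, 0.43, 2.47)
        assert pi == pytest.approx(expected, abs=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_auto_sorts_unsorted_input(self):
        unsorted = Lottery([-50, 0, -5], [0.1, 0.7, 0.2])
        ordered = Lottery([0, -5, -50], [0.7, 0.2, 0.1])
        assert decision_weights(unsorted, 0.5, 2.0) == pytest.approx(
            decision_weights(ordered, 0.5, 2.0)
        )

    def test_telescoping_on_random_lotteries(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            lot = random_loss_lottery(rng)
            gamma = rng.uniform(0.1, 1.0)
            delta = rng.uniform(0.1, 10.0)
            pi = decision_weights(lot, gamma, delta)
            outs, expected = oracle_decision_weights(lot.outcomes, lot.probs, gamma, delta)
            assert pi == pytest.approx(expected, abs=1e-9)


class TestValuation:
    def test_reduces_to_expected_value_at_identity(self):
        lot = Lottery([-18, 0], [0.15, 0.85])
        p = CPTParams(alpha=1, gamma=1, delta=1, g=0.5)
        assert valuation(lot, p) == pytest.approx(-2.70, abs=1e-12)

    def test_zero_prospect(self):
        p = CPTParams(alpha=0.79, gamma=0.43, delta=2.47, g=0.12)
        assert valuation(Lottery([0], [1.0]), p) == 0.0

    def test_matches_term_by_term_oracle(self):
        p = CPTParams(alpha=0.79, gamma=0.43, delta=2.47, g=0.12)
        lot = Lottery([-50, 0], [0.05, 0.95])
        outs, weights = oracle_decision_weights(lot.outcomes, lot.probs, p.gamma, p.delta)
        expected = sum(-((-x) ** p.alpha) * w for x, w in zip(outs, weights))
        assert valuation(lot, p) == pytest.approx(expected, abs=1e-12)

    def test_identity_equals_ev_on_random_lotteries(self):
        rng = np.random.default_rng(7)
        p = CPTParams(alpha=1, gamma=1, delta=1, g=0.5)
        for _ in range(200):
            lot = random_loss_lottery(rng)
            assert valuation(lot, p) == pytest.approx(expected_value(lot), abs=1e-9)


class TestChoiceRule:
    A = Lottery([-18, 0], [0.15, 0.85])
    B = Lottery([-50, 0], [0.05, 0.95])

    def test_pure_guessing_is_half(self):
        p = CPTParams(alpha=0.8, gamma=0.5, delta=1.0, g=1.0)
        assert choice_prob(self.A, self.B, p) == pytest.approx(0.5)

    def test_equal_valuations_symmetric(self):
        p = CPTParams(alpha=1, gamma=1, delta=1, g=0.07)
        assert choice_prob(self.A, self.A, p) == pytest.approx(0.5)

    def test_logistic_of_difference(self):
        # V(A)=-2.70, V(B)=-2.50, no guessing
        expected = 1.0 / (1.0 + math.exp(-(-2.70 - -2.50)))
        assert softmax_choice_prob(-2.70, -2.50, g=0.0) == pytest.approx(expected, abs=1e-12)
        assert softmax_choice_prob(-2.70, -2.50, g=0.0) == pytest.approx(0.4502, abs=1e-4)

    @pytest.mark.parametrize("rule", list(ChoiceRule))
    def test_complementarity(self, rule):
        rng = np.random.default_rng(5)
        p = CPTParams(alpha=0.7, gamma=0.5, delta=2.0, g=0.1, phi=0.8)
        for _ in range(50):
            a = random_loss_lottery(rng)
            b = random_loss_lottery(rng)
            s = choice_prob(a, b, p, rule) + choice_prob(b, a, p, rule)
            assert s == pytest.approx(1.0, abs=1e-9)

    def test_bounded_by_guessing_floor(self):
        p = CPTParams(alpha=1, gamma=1, delta=1, g=0.2)
        big = Lottery([-1000, 0], [0.9, 0.1])
        small = Lottery([-1, 0], [0.5, 0.5])
        assert choice_prob(big, small, p) == pytest.approx(0.1, abs=1e-6)
        assert choice_prob(small, big, p) == pytest.approx(0.9, abs=1e-6)

    def test_monotone_in_value_difference(self):
        vbs = np.linspace(-30, 0, 40)
        # as V(B) improves toward 0, choosing A must become less likely
        probs = [softmax_choice_prob(-10.0, vb, g=0.1) for vb in vbs]
        assert np.all(np.diff(probs) < 0)

    def test_sensitivity_rules_require_phi(self):
        p = CPTParams(alpha=0.7, gamma=0.5, delta=2.0, g=0.1)
        with pytest.raises(ValueError):
            choice_prob(self.A, self.B, p, ChoiceRule.SENSITIVITY_ONLY)

    def test_extreme_values_do_not_overflow(self):
        p = CPTParams(alpha=1.0, gamma=1.0, delta=1.0, g=1e-6)
        huge = Lottery([-1e6], [1.0])
        tiny = Lottery([-1e-6, 0], [0.5, 0.5])
        assert 0.0 <= choice_prob(huge, tiny, p) <= 1.0


def test_params_bounds_enforced():
    with pytest.raises(ValueError):
        CPTParams(alpha=1.2, gamma=0.5, delta=1.0, g=0.1)
    with pytest.raises(ValueError):
        CPTParams(alpha=0.5, gamma=0.5, delta=11.0, g=0.1)
    with pytest.raises(ValueError):
        CPTParams(alpha=0.5, gamma=0.5, delta=1.0, g=0.0)
    with pytest.raises(ValueError):
        CPTParams(alpha=0.5, gamma=0.5, delta=1.0, g=0.1, phi=-1.0)
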