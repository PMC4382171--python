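"""Deviance, grid search, simplex refinement, BIC, and rule comparison."""

import itertools
import math

import numpy as np
import pytest

from affectcpt import (
    ChoiceRecord,
    ChoiceRule,
    CPTParams,
    Domain,
    Lottery,
    LotteryProblem,
    bic_score,
    chance_g2,
    compare_rules,
    fit_participant,
    g2,
    grid_search,
    per_trial_choice_probs,
    refine,
)
from affectcpt.estimator import CPTChoiceModel
from affectcpt.fitting import bic
from affectcpt.synth import SimulatedParticipant, simulate_choices

A = Lottery([0, -18], [0.85, 0.15])
B = Lottery([0, -50], [0.95, 0.05])
PROBLEM = LotteryProblem(1, Domain.AFFECT_POOR, A, B)


def make_choices(chosen_seq, template_id=1, domain=Domain.AFFECT_POOR):
    recs = []
    for i, ch in enumerate(chosen_seq):
        recs.append(
            ChoiceRecord(
                participant_id=1,
                template_id=template_id,
                domain=domain,
                presentation_index=1 + (i % 2),
                evaluated_option="A" if i % 2 == 0 else "B",
                chosen=ch,
            )
        )
    return recs


class TestG2:
    def test_chance_deviance_84_trials(self):
        params = CPTParams(alpha=0.5, gamma=0.5, delta=1.0, g=1.0)
        choices = make_choices(["A", "B"] * 42)
        val = g2(choices, [PROBLEM], params)
        assert val == pytest.approx(116.45, abs=0.01)
        assert val == pytest.approx(chance_g2(84), abs=1e-9)

    def test_matches_independent_per_trial_loop(self):
        params = CPTParams(alpha=0.79, gamma=0.43, delta=2.47, g=0.12)
        choices = make_choices(["A", "B", "A", "A", "B"])
        probs = per_trial_choice_probs(choices, [PROBLEM], params)
        oracle = -2.0 * sum(math.log(p) for p in probs)
        assert g2(choices, [PROBLEM], params) == pytest.approx(oracle, abs=1e-9)

    def test_hand_computed_two_trials(self):
        # probabilities 0.8 and 0.6 for the observed choices
        assert -2 * (math.log(0.8) + math.log(0.6)) == pytest.approx(1.4679, abs=1e-4)

    def test_perfect_prediction_zero(self):
        # g ~ 0 and a huge value gap makes the observed choice near-certain
        big_gap = LotteryProblem(
            2, Domain.AFFECT_POOR,
            Lottery([0, -1], [0.1, 0.9]),
            Lottery([0, -1000], [0.95, 0.05]),
        )
        params = CPTParams(alpha=1.0, gamma=1.0, delta=1.0, g=1e-6)
        choices = make_choices(["A"], template_id=2)
        assert g2(choices, [big_gap], params) == pytest.approx(0.0, abs=1e-3)

    def test_floor_keeps_deviance_finite(self):
        # sensitivity rule with huge phi predicts ~0 for the observed choice
        params = CPTParams(alpha=1.0, gamma=1.0, delta=1.0, g=1e-6, phi=10.0)
        big_gap = LotteryProblem(
            2, Domain.AFFECT_POOR,
            Lottery([0, -1], [0.1, 0.9]),
            Lottery([0, -1000], [0.95, 0.05]),
        )
        choices = make_choices(["B"], template_id=2)
        val = g2(choices, [big_gap], params, rule=ChoiceRule.SENSITIVITY_ONLY)
        assert np.isfinite(val)
        assert val <= -2 * math.log(1e-12) + 1e-6


class TestGridSearch:
    def test_returns_20_sorted(self):
        choices = make_choices(["A", "B"] * 10)
        top = grid_search(choices, [PROBLEM])
        assert len(top) == 20
        scores = [s for _, s in top]
        assert scores == sorted(scores)

    def test_guessing_data_best_at_most_chance(self):
        rng = np.random.default_rng(0)
        choices = make_choices(rng.choice(["A", "B"], size=84))
        top = grid_search(choices, [PROBLEM])
        assert top[0][1] <= chance_g2(84) + 1e-9

    def test_matches_brute_force_on_mini_grid(self):
        mini = {
            "alpha": (0.3, 0.6, 1.0),
            "gamma": (0.3, 0.6, 1.0),
            "delta": (0.5, 1.0, 2.0),
            "g": (0.05, 0.3, 0.9),
        }
        choices = make_choices(["A", "B", "A", "A", "B", "B", "A", "B"])
        top = grid_search(choices, [PROBLEM], grid_spec=mini, n_top=81)
        # independent brute force in the same product order
        oracle = []
        for a, gm, d, gg in itertools.product(
            mini["alpha"], mini["gamma"], mini["delta"], mini["g"]
        ):
            params = CPTParams(alpha=a, gamma=gm, delta=d, g=gg)
            oracle.append(((a, gm, d, gg), g2(choices, [PROBLEM], params)))
        oracle.sort(key=lambda t: t[1])
        assert len(top) == 81
        for (params, score), (combo, oscore) in zip(top, oracle):
            assert score == pytest.approx(oscore, abs=1e-9)
            assert (params.alpha, params.gamma, params.delta, params.g) == combo

    def test_small_grid_returns_all_with_warning(self):
        tiny = {"alpha": (0.5, 1.0), "gamma": (0.5, 1.0), "delta": (1.0,), "g": (0.1, 0.9)}
        choices = make_choices(["A", "B"] * 4)
        with pytest.warns(UserWarning, match="grid holds only"):
            top = grid_search(choices, [PROBLEM], grid_spec=tiny)
        assert len(top) == 8


class TestRefine:
    def test_never_worse_than_start(self):
        choices = make_choices(["A", "B", "A", "B", "A", "A"])
        start = CPTParams(alpha=0.5, gamma=0.5, delta=1.0, g=0.3)
        res = refine(start, choices, [PROBLEM])
        assert res.g2 <= g2(choices, [PROBLEM], start) + 1e-9

    def test_chance_start_stays_at_most_chance(self):
        rng = np.random.default_rng(3)
        choices = make_choices(rng.choice(["A", "B"], size=84))
        start = CPTParams(alpha=0.5, gamma=0.5, delta=1.0, g=0.999999)
        res = refine(start, choices, [PROBLEM])
        assert res.g2 <= chance_g2(84) + 1e-6

    def test_result_respects_bounds(self):
        choices = make_choices(["A"] * 20)
        start = CPTParams(alpha=1.0, gamma=1.0, delta=10.0, g=0.02)
        res = refine(start, choices, [PROBLEM])
        p = res.params
        assert 0 < p.alpha <= 1 + 1e-9
        assert 0 < p.gamma <= 1 + 1e-9
        assert 0 < p.delta <= 10 + 1e-9
        assert 0 < p.g <= 1 + 1e-9


class TestFitParticipant:
    def test_ev_maximizer_recovers_near_linear(self, one_participant_design):
        ranking, wtp, problems, trials = one_participant_design
        p = CPTParams(alpha=1.0, gamma=1.0, delta=1.0, g=0.02)
        part = SimulatedParticipant(1, ranking, wtp, p, p)
        rng = np.random.default_rng(11)
        recs = simulate_choices(part, list(trials) * 10, problems, rng=rng)
        rich = [r for r in recs if r.domain is Domain.AFFECT_RICH]
        fit = fit_participant(rich, problems)
        assert fit.params.alpha > 0.8
        assert fit.params.gamma > 0.8
        assert fit.per_trial_prob.mean() > 0.8

    def test_fair_coin_choices_at_most_chance(self):
        rng = np.random.default_rng(21)
        choices = make_choices(rng.choice(["A", "B"], size=84))
        fit = fit_participant(choices, [PROBLEM])
        assert fit.g2 <= chance_g2(84) + 1e-6

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        choices = make_choices(rng.choice(["A", "B"], size=30))
        f1 = fit_participant(choices, [PROBLEM])
        f2 = fit_participant(choices, [PROBLEM])
        assert f1.params == f2.params
        assert f1.g2 == f2.g2
        assert np.array_equal(f1.per_trial_prob, f2.per_trial_prob)

    def test_g2_consistent_with_per_trial_probs(self):
        rng = np.random.default_rng(2)
        choices = make_choices(rng.choice(["A", "B"], size=40))
        fit = fit_participant(choices, [PROBLEM])
        assert fit.g2 == pytest.approx(-2 * np.sum(np.log(fit.per_trial_prob)), abs=1e-6)
        assert np.all(fit.per_trial_prob > 0)
        assert np.all(fit.per_trial_prob <= 1)

    def test_empty_choice_set_rejected(self):
        with pytest.raises(ValueError):
            fit_participant([], [PROBLEM])

    def test_mixed_participants_rejected(self):
        recs = make_choices(["A", "B"])
        other = ChoiceRecord(2, 1, Domain.AFFECT_POOR, 1, "A", "B")
        with pytest.raises(ValueError):
            fit_participant(recs + [other], [PROBLEM])


class TestBIC:
    def test_formula(self):
        assert bic_score(100.0, 4, 84) == pytest.approx(100 + 4 * math.log(84), abs=1e-9)

    def test_zero_parameters(self):
        assert bic_score(55.0, 0, 84) == 55.0

    def test_penalty_monotone_in_k(self):
        assert bic_score(100.0, 4, 84) < bic_score(100.0, 5, 84)

    def test_rule_parameter_counts(self):
        assert len(ChoiceRule.GUESS_ONLY.free_params) == 4
        assert len(ChoiceRule.SENSITIVITY_ONLY.free_params) == 4
        assert len(ChoiceRule.BOTH.free_params) == 5


class TestCompareRules:
    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(17)
        choices = make_choices(rng.choice(["A", "B"], size=20))
        ranked = compare_rules(choices, [PROBLEM])
        assert sorted(f.rule for f in ranked) == sorted(ChoiceRule)
        bics = [f.bic for f in ranked]
        assert bics == sorted(bics)

    def test_guessing_data_prefers_guessing_rule(self, one_participant_design):
        """Self-consistency: data generated with substantial guessing should
        rank the guessing rule first more often than not."""
        ranking, wtp, problems, trials = one_participant_design
        p = CPTParams(alpha=0.8, gamma=0.6, delta=1.0, g=0.3)
        part = SimulatedParticipant(1, ranking, wtp, p, p)
        wins = 0
        n_reps = 20
        rng = np.random.default_rng(100)
        for _ in range(n_reps):
            recs = simulate_choices(part, list(trials) * 10, problems, rng=rng)
            rich = [r for r in recs if r.domain is Domain.AFFECT_RICH]
            ranked = compare_rules(rich, problems)
            wins += ranked[0].rule is ChoiceRule.GUESS_ONLY
        assert wins > n_reps / 2

    def test_softmax_data_sensitivity_not_worse(self, one_participant_design):
        """Data from a pure softmax (no guessing) should not favor the
        guessing rule over the sensitivity rules in most replicates."""
        ranking, wtp, problems, trials = one_participant_design
        p = CPTParams(alpha=0.8, gamma=0.6, delta=1.0, g=1e-6, phi=1.0)
        part = SimulatedParticipant(1, ranking, wtp, p, p)
        wins = 0
        n_reps = 20
        rng = np.random.default_rng(200)
        for _ in range(n_reps):
            recs = simulate_choices(
                part, list(trials) * 10, problems,
                rule=ChoiceRule.SENSITIVITY_ONLY, rng=rng,
            )
            rich = [r for r in recs if r.domain is Domain.AFFECT_RICH]
            fits = {f.rule: f for f in compare_rules(rich, problems)}
            best_sens = min(
                fits[ChoiceRule.SENSITIVITY_ONLY].bic, fits[ChoiceRule.BOTH].bic
            )
            wins += best_sens <= fits[ChoiceRule.GUESS_ONLY].bic + 1e-6
        assert wins > n_reps / 2


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        model = CPTChoiceModel(rule="guess_only", n_starts=5)
        assert model.get_params()["rule"] == "guess_only"
        model.set_params(n_starts=3)
        assert model.n_starts == 3

    def test_fit_predict_roundtrip(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([
            -rng.uniform(5, 50, 40), rng.uniform(0.4, 0.9, 40),
            -rng.uniform(5, 50, 40), rng.uniform(0.05, 0.3, 40),
        ])
        y = rng.integers(0, 2, 40)
        model = CPTChoiceModel(n_starts=5).fit(X, y)
        proba = model.predict_proba(X)
        assert proba.shape == (40, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(model.predict(X)) <= {0, 1}
        assert model.g2_ <= chance_g2(40) + 1e-6
        assert model.bic_ == pytest.approx(model.g2_ + 4 * math.log(40))

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            CPTChoiceModel().predict_proba(np.zeros((2, 4)))


def test_fit_result_bic_matches_helper():
    rng = np.random.default_rng(31)
    choices = make_choices(rng.choice(["A", "B"], size=24))
    fit = fit_participant(choices, [PROBLEM])
    assert fit.bic == pytest.approx(bic(fit), abs=1e-12)
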