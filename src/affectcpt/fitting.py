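"""Per-participant, per-domain CPT fitting and choice-rule comparison.

Thin record-level wrappers over :class:`affectcpt.estimator.CPTChoiceModel`:
they resolve :class:`~affectcpt.lotteries.ChoiceRecord` rows against a
problem set, run the grid-search + simplex fit, and package the result with
its deviance (G^2), BIC, and per-trial predicted probabilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .cpt import ChoiceRule, CPTParams, choice_prob
from .estimator import (
    PROB_FLOOR,
    CPTChoiceModel,
    TrialData,
    chance_g2,
    refine_start,
    top_grid_points,
)
from .lotteries import ChoiceRecord, Domain, Lottery, LotteryProblem

__all__ = [
    "FitResult",
    "g2",
    "per_trial_choice_probs",
    "grid_search",
    "refine",
    "fit_participant",
    "bic",
    "bic_score",
    "compare_rules",
    "chance_g2",
]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: CPTParams
    g2: float
    n_trials: int
    bic: float
    rule: ChoiceRule
    start_points_used: int
    converged: bool
    per_trial_prob: np.ndarray = field(repr=False)
    grid_best_g2: Optional[float] = None

    def to_dict(self) -> dict:
        p = {
            "alpha": self.params.alpha,
            "gamma": self.params.gamma,
            "delta": self.params.delta,
            "g": self.params.g,
            "phi": self.params.phi,
        }
        return {
            "rule": self.rule.value,
            "params": p,
            "g2": self.g2,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "start_points_used": self.start_points_used,
            "converged": self.converged,
            "grid_best_g2": self.grid_best_g2,
            "per_trial_prob": [float(v) for v in self.per_trial_prob],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


ProblemIndex = Mapping[tuple[int, Domain], LotteryProblem]


def index_problems(problems: Iterable[LotteryProblem]) -> dict[tuple[int, Domain], LotteryProblem]:
    """Index problems by (template_id, domain); duplicates rejected."""
    if isinstance(problems, Mapping):
        return dict(problems)
    out: dict[tuple[int, Domain], LotteryProblem] = {}
    for prob in problems:
        key = (prob.template_id, prob.domain)
        if key in out:
            raise ValueError(f"duplicate problem for {key}")
        out[key] = prob
    return out


def _trial_data(choices: Sequence[ChoiceRecord], problems) -> TrialData:
    """Resolve choice records to a TrialData, two-branch vectorized if possible."""
    idx = index_problems(problems)
    pairs, y = [], []
    for rec in choices:
        key = (rec.template_id, rec.domain)
        if key not in idx:
            raise KeyError(f"no problem for template {rec.template_id} / {rec.domain}")
        prob = idx[key]
        pairs.append((prob.option_a, prob.option_b))
        y.append(rec.chosen == "A")
    try:
        rows = [(*a.loss_branch(), *b.loss_branch()) for a, b in pairs]
    except ValueError:
        return TrialData(y, pairs=pairs)
    return TrialData(y, X=np.asarray(rows, dtype=float))


def per_trial_choice_probs(
    choices: Sequence[ChoiceRecord],
    problems,
    params: CPTParams,
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
) -> np.ndarray:
    """Predicted probability of each observed choice under ``params``."""
    idx = index_problems(problems)
    rule = ChoiceRule(rule)
    out = np.empty(len(choices))
    for i, rec in enumerate(choices):
        prob = idx[(rec.template_id, rec.domain)]
        p_a = choice_prob(prob.option_a, prob.option_b, params, rule)
        out[i] = p_a if rec.chosen == "A" else 1.0 - p_a
    return out


def g2(
    choices: Sequence[ChoiceRecord],
    problems,
    params: CPTParams,
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
    floor: float = PROB_FLOOR,
) -> float:
    """Deviance ``-2 sum_i ln f_i(y | theta)`` of observed choices.

    ``f`` is the choice-rule probability of the chosen option.  Predicted
    probabilities are floored at ``floor`` before the log so a zero
    prediction for an observed choice yields a large finite deviance.
    """
    p = per_trial_choice_probs(choices, problems, params, rule)
    return float(-2.0 * np.sum(np.log(np.clip(p, floor, 1.0))))


def grid_search(
    choices: Sequence[ChoiceRecord],
    problems,
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
    grid_spec: Optional[dict] = None,
    n_top: int = 20,
) -> list[tuple[CPTParams, float]]:
    """The ``n_top`` (default 20) best grid points, ascending by G^2.

    If the grid holds fewer points than ``n_top``, all are returned.
    """
    data = _trial_data(choices, problems)
    top = top_grid_points(data, ChoiceRule(rule), grid_spec, n_top)
    return [(_as_params(p), s) for p, s in top]


def refine(
    start: CPTParams,
    choices: Sequence[ChoiceRecord],
    problems,
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
    **simplex_options,
) -> FitResult:
    """Simplex refinement from one start; never worse than the start."""
    rule = ChoiceRule(rule)
    data = _trial_data(choices, problems)
    start_dict = {n: getattr(start, n) for n in rule.free_params}
    params, g2_val, converged = refine_start(data, rule, start_dict, **simplex_options)
    return _result(params, g2_val, data, rule, start_points_used=1, converged=converged)


def fit_participant(
    choices: Sequence[ChoiceRecord],
    problems,
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
    grid_spec: Optional[dict] = None,
    n_starts: int = 20,
) -> FitResult:
    """Grid search + simplex fit of one participant's choices in one domain.

    Deterministic for a fixed dataset and grid; the returned G^2 never
    exceeds the chance deviance (guessing is nested in the model).
    """
    if not choices:
        raise ValueError("empty choice set")
    participants = {c.participant_id for c in choices}
    domains = {c.domain for c in choices}
    if len(participants) > 1 or len(domains) > 1:
        raise ValueError("fit_participant expects one participant and one domain")
    data = _trial_data(choices, problems)
    model = CPTChoiceModel(rule=ChoiceRule(rule).value, grid=grid_spec, n_starts=n_starts)
    model._fit_data(data)
    return _fit_result_from_model(model)


def bic_score(g2_value: float, k: int, n: int) -> float:
    """``G^2 + k ln(n)``: deviance plus the parameter-count penalty."""
    return g2_value + k * math.log(n) if k else g2_value


def bic(fit: FitResult) -> float:
    """BIC of a fit; k is the number of free parameters of its rule."""
    return bic_score(fit.g2, len(fit.rule.free_params), fit.n_trials)


def compare_rules(
    choices: Sequence[ChoiceRecord],
    problems,
    rules: Sequence[ChoiceRule] = (
        ChoiceRule.GUESS_ONLY,
        ChoiceRule.SENSITIVITY_ONLY,
        ChoiceRule.BOTH,
    ),
    grid_spec: Optional[dict] = None,
) -> list[FitResult]:
    """Fit each choice-rule variant and rank them by ascending BIC."""
    fits = [fit_participant(choices, problems, rule, grid_spec=grid_spec) for rule in rules]
    return sorted(fits, key=lambda f: f.bic)


def _as_params(d: dict) -> CPTParams:
    return CPTParams(
        alpha=d["alpha"],
        gamma=d["gamma"],
        delta=d["delta"],
        g=d.get("g", 1e-6),
        phi=d.get("phi"),
    )


def _result(params_dict, g2_val, data, rule, start_points_used, converged, grid_best=None):
    params = _as_params(params_dict)
    va, vb = data.valuations(params.alpha, params.gamma, params.delta)
    from .estimator import observed_choice_probs

    p = observed_choice_probs(
        va, vb, data.y, params_dict.get("g", 0.0), params_dict.get("phi", 1.0)
    )
    k = len(rule.free_params)
    return FitResult(
        params=params,
        g2=float(g2_val),
        n_trials=len(data),
        bic=bic_score(float(g2_val), k, len(data)),
        rule=rule,
        start_points_used=start_points_used,
        converged=converged,
        per_trial_prob=np.clip(p, PROB_FLOOR, 1.0),
        grid_best_g2=grid_best,
    )


def _fit_result_from_model(model: CPTChoiceModel) -> FitResult:
    return FitResult(
        params=model.params_,
        g2=model.g2_,
        n_trials=model.n_trials_,
        bic=model.bic_,
        rule=model.rule_,
        start_points_used=model.start_points_used_,
        converged=model.converged_,
        per_trial_prob=np.clip(model.per_trial_prob_, PROB_FLOOR, 1.0),
        grid_best_g2=model.grid_best_g2_,
    )
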