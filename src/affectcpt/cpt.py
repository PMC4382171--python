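"""Cumulative prospect theory for losses and the choice-rule variants.

The model transforms loss magnitudes through a power value function
``v(x) = -(-x)**alpha`` and probabilities through a two-parameter weighting
function ``w(p) = delta * p**gamma / (delta * p**gamma + (1-p)**gamma)``
(gamma: curvature / probability sensitivity; delta: elevation / risk
aversion).  Ranked outcomes receive decision weights as differences of ``w``
at cumulative probabilities, and a lottery's valuation is the
decision-weighted sum of subjective values.

Choice probabilities come from a softmax combined with a guessing mixture:
``p(A,B) = (1-g) * exp(V(A)) / (exp(V(A)) + exp(V(B))) + g/2``.  Two
variants replace or augment the guessing parameter with a choice-sensitivity
parameter ``phi`` scaling the valuation difference.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .lotteries import Lottery, sort_by_badness

__all__ = [
    "ChoiceRule",
    "CPTParams",
    "value_fn",
    "weight_fn",
    "decision_weights",
    "valuation",
    "choice_prob",
    "softmax_choice_prob",
]

# Open lower bounds (0 < alpha, ...) are implemented as >= 1e-6.
EPS_LOWER = 1e-6
# Softmax operates on raw currency-scale valuations (no rescaling), so the
# exponent difference is clipped to keep exp() finite.
_CLIP = 500.0

# Parameter intervals (lower, upper); lower bounds are open in the model and
# enforced as EPS_LOWER.
BOUNDS = {
    "alpha": (EPS_LOWER, 1.0),
    "gamma": (EPS_LOWER, 1.0),
    "delta": (EPS_LOWER, 10.0),
    "g": (EPS_LOWER, 1.0),
    "phi": (EPS_LOWER, 10.0),
}


class ChoiceRule(str, enum.Enum):
    """How valuations map to choice probabilities.

    GUESS_ONLY: softmax plus a guessing mixture weight g (the study's rule).
    SENSITIVITY_ONLY: softmax with sensitivity phi, no guessing.
    BOTH: sensitivity-scaled softmax plus guessing.
    """

    GUESS_ONLY = "guess_only"
    SENSITIVITY_ONLY = "sensitivity_only"
    BOTH = "both"

    @property
    def free_params(self) -> tuple[str, ...]:
        base = ("alpha", "gamma", "delta")
        if self is ChoiceRule.GUESS_ONLY:
            return base + ("g",)
        if self is ChoiceRule.SENSITIVITY_ONLY:
            return base + ("phi",)
        return base + ("g", "phi")


@dataclass(frozen=True)
class CPTParams:
    """CPT parameter set.

    alpha: outcome sensitivity, 0 < alpha <= 1 (1 = linear value function).
    gamma: probability sensitivity, 0 < gamma <= 1 (lower = more inverse-S).
    delta: weighting elevation, 0 < delta <= 10 (higher = more risk averse).
    g: guessing probability, 0 < g <= 1.
    phi: optional choice sensitivity (> 0), used by the rule variants.
    """

    alpha: float
    gamma: float
    delta: float
    g: float = EPS_LOWER
    phi: Optional[float] = None

    def __post_init__(self):
        for name in ("alpha", "gamma", "g"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 < self.delta <= 10.0):
            raise ValueError(f"delta must be in (0, 10], got {self.delta}")
        if self.phi is not None and self.phi <= 0.0:
            raise ValueError(f"phi must be > 0, got {self.phi}")


def value_fn(x, alpha: float):
    """Subjective value of a loss, ``v(x) = -(-x)**alpha`` with v(0) = 0.

    Convex for losses when alpha < 1 (diminishing outcome sensitivity).
    Accepts scalars or arrays; positive outcomes are rejected.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x > 0):
        raise ValueError("loss-domain value function requires x <= 0")
    out = -np.power(-x, alpha)
    return float(out) if out.ndim == 0 else out


def weight_fn(p, gamma: float, delta: float):
    """Probability weighting ``w(p) = d*p**g / (d*p**g + (1-p)**g)``.

    Endpoints are exact: w(0) = 0, w(1) = 1.  Strictly increasing on (0, 1)
    for valid gamma, delta.  Accepts scalars or arrays.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    num = delta * np.power(p, gamma)
    w = num / (num + np.power(1.0 - p, gamma))
    return float(w) if w.ndim == 0 else w


def decision_weights(lottery: Lottery, gamma: float, delta: float) -> np.ndarray:
    """Rank-dependent decision weight per branch of a loss lottery.

    With outcomes ranked 0 >= x_1 >= ... >= x_k, the weight of x_j is
    ``w(p_j + ... + p_k) - w(p_{j+1} + ... + p_k)``: the weighted probability
    of an outcome at least as bad as x_j minus that of a strictly worse one.
    Input is auto-sorted by badness; weights are returned in the sorted
    order and sum to w(1) = 1 for a complete lottery.
    """
    lot = sort_by_badness(lottery)
    probs = np.asarray(lot.probs, dtype=float)
    # tail[j] = p_j + ... + p_k (suffix sums); tail[k+1] = 0.  The full tail
    # is exactly 1 for a complete lottery; pinning it avoids the unbounded
    # slope of w at p = 1 amplifying float summation error.
    tail = np.concatenate([np.cumsum(probs[::-1])[::-1], [0.0]])
    tail = np.clip(tail, 0.0, 1.0)
    tail[0] = 1.0
    w = weight_fn(tail, gamma, delta)
    return w[:-1] - w[1:]


def valuation(lottery: Lottery, params: CPTParams) -> float:
    """Overall valuation ``V = sum_j v(x_j) * pi_j`` of a loss lottery.

    With alpha = gamma = delta = 1 this reduces to the expected value.
    """
    lot = sort_by_badness(lottery)
    v = value_fn(np.asarray(lot.outcomes), params.alpha)
    pi = decision_weights(lot, params.gamma, params.delta)
    return float(np.dot(np.atleast_1d(v), pi))


def softmax_choice_prob(v_a, v_b, g: float = 0.0, phi: float = 1.0):
    """Probability of choosing A from valuations, on the raw value scale.

    ``(1-g) * expit(phi * (V(A) - V(B))) + g/2``; the exponent difference is
    clipped to +/-500 for overflow safety.  Vectorized.
    """
    d = np.clip(phi * (np.asarray(v_a, dtype=float) - np.asarray(v_b, dtype=float)), -_CLIP, _CLIP)
    p = (1.0 - g) * expit(d) + g / 2.0
    return float(p) if p.ndim == 0 else p


def choice_prob(
    option_a: Lottery,
    option_b: Lottery,
    params: CPTParams,
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
) -> float:
    """Probability that option A is chosen over option B under ``rule``.

    guess_only uses the guessing mixture with unit sensitivity; the
    sensitivity rules require ``params.phi``.  Satisfies
    ``choice_prob(A, B) + choice_prob(B, A) == 1`` and, for rules with g,
    lies in [g/2, 1 - g/2].
    """
    rule = ChoiceRule(rule)
    v_a = valuation(option_a, params)
    v_b = valuation(option_b, params)
    if rule is ChoiceRule.GUESS_ONLY:
        return softmax_choice_prob(v_a, v_b, g=params.g, phi=1.0)
    if params.phi is None:
        raise ValueError(f"rule {rule.value!r} requires phi")
    if rule is ChoiceRule.SENSITIVITY_ONLY:
        return softmax_choice_prob(v_a, v_b, g=0.0, phi=params.phi)
    return softmax_choice_prob(v_a, v_b, g=params.g, phi=params.phi)
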