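"""Domain types for two-option loss lotteries and choice data.

A lottery here is a loss prospect: each branch is a non-positive outcome
(currency units; the design uses each participant's willingness-to-pay to
avoid a side effect) occurring with some probability.  Problems pair a
smaller-but-likelier loss against a larger-but-rarer one, in two domains:
affect-rich (drug side effects) and affect-poor (monetarily matched losses).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Domain",
    "Lottery",
    "LotteryProblem",
    "ChoiceRecord",
    "expected_value",
    "sort_by_badness",
]

_PROB_TOL = 1e-9


class Domain(str, enum.Enum):
    """Problem domain: side-effect outcomes vs matched monetary losses."""

    AFFECT_RICH = "affect_rich"
    AFFECT_POOR = "affect_poor"


@dataclass(frozen=True)
class Lottery:
    """A loss prospect: outcomes ``x_i <= 0`` with probabilities ``p_i``.

    Probabilities must sum to one; zero-outcome branches are kept explicitly
    so rank-dependent weighting applies uniformly (the zero outcome is
    value-neutral).  Branches with probability exactly zero are dropped at
    construction: they are unobservable and would create degenerate ties in
    the outcome ranking.
    """

    outcomes: tuple[float, ...]
    probs: tuple[float, ...]

    def __init__(self, outcomes: Sequence[float], probs: Sequence[float]):
        outcomes = tuple(float(x) for x in outcomes)
        probs = tuple(float(p) for p in probs)
        if len(outcomes) != len(probs):
            raise ValueError("outcomes and probs must have equal length")
        if not outcomes:
            raise ValueError("lottery needs at least one branch")
        kept = [(x, p) for x, p in zip(outcomes, probs) if p != 0.0]
        if not kept:
            raise ValueError("all branches have probability zero")
        outcomes = tuple(x for x, _ in kept)
        probs = tuple(p for _, p in kept)
        if any(x > 0 for x in outcomes):
            raise ValueError(f"loss-domain lottery requires outcomes <= 0, got {outcomes}")
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"probabilities must lie in [0, 1], got {probs}")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)!r}")
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "probs", probs)

    @property
    def n_branches(self) -> int:
        return len(self.outcomes)

    def loss_branch(self) -> tuple[float, float]:
        """Return (magnitude, probability) of the single non-zero loss.

        Only defined for the two-branch design prospects (one loss, rest
        zero); a sure loss ``{x @ 1}`` also qualifies.
        """
        nonzero = [(x, p) for x, p in zip(self.outcomes, self.probs) if x != 0.0]
        if len(nonzero) > 1:
            raise ValueError("lottery has more than one non-zero loss branch")
        if not nonzero:
            return 0.0, 0.0
        return nonzero[0]


@dataclass(frozen=True)
class LotteryProblem:
    """A matched pair of loss lotteries presented as a binary choice.

    Exactly one option carries the smaller-magnitude, higher-probability loss
    (the other the larger, rarer loss).  The affect-poor twin of an
    affect-rich problem shares its probabilities; its magnitudes are the
    participant's WTPs for the labelled side effects.
    """

    template_id: int
    domain: Domain
    option_a: Lottery
    option_b: Lottery
    side_effect_labels: Optional[tuple[str, str]] = None

    def __post_init__(self):
        xa, pa = self.option_a.loss_branch()
        xb, pb = self.option_b.loss_branch()
        small_big = abs(xa) < abs(xb) and pa > pb
        big_small = abs(xa) > abs(xb) and pa < pb
        if not (small_big or big_small):
            raise ValueError(
                "one option must carry the smaller-magnitude/higher-probability "
                f"loss and the other the larger/rarer one; got A=({xa}@{pa}), B=({xb}@{pb})"
            )

    def option(self, which: str) -> Lottery:
        if which == "A":
            return self.option_a
        if which == "B":
            return self.option_b
        raise KeyError(which)


@dataclass(frozen=True)
class ChoiceRecord:
    """One choice trial.

    ``evaluated_option`` is the option shown alone during the evaluation
    phase; each problem appears twice per domain, once with each option
    evaluated.
    """

    participant_id: int
    template_id: int
    domain: Domain
    presentation_index: int  # 1 or 2
    evaluated_option: str  # "A" or "B"
    chosen: str  # "A" or "B"

    def __post_init__(self):
        if self.presentation_index not in (1, 2):
            raise ValueError("presentation_index must be 1 or 2")
        if self.evaluated_option not in ("A", "B"):
            raise ValueError("evaluated_option must be 'A' or 'B'")
        if self.chosen not in ("A", "B"):
            raise ValueError("chosen must be 'A' or 'B'")


def expected_value(lottery: Lottery) -> float:
    """Expected value ``sum(p_i * x_i)`` of a loss prospect (<= 0)."""
    return float(np.dot(lottery.probs, lottery.outcomes))


def sort_by_badness(lottery: Lottery) -> Lottery:
    """Order branches from best (0) to worst (most negative loss).

    Rank-dependent weighting is defined on outcomes ordered
    ``0 >= x_1 >= ... >= x_k``; probabilities are permuted in lockstep.
    Idempotent; preserves the multiset of (outcome, probability) pairs.
    """
    order = np.argsort([-x for x in lottery.outcomes], kind="stable")
    return Lottery(
        [lottery.outcomes[i] for i in order],
        [lottery.probs[i] for i in order],
    )
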