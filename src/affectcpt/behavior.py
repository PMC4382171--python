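"""Behavioral summary statistics: EV-maximization and preference reversals.

Because the affect-poor twin of each affect-rich problem is monetarily
identical, choosing different options in the matched pair is a preference
reversal; the rate of choosing the option with the higher expected value
quantifies sensitivity to the probability/magnitude trade-off in each
domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import index_problems
from .lotteries import ChoiceRecord, Domain, expected_value

__all__ = [
    "BehaviorSummary",
    "ev_maximization_rate",
    "preference_reversal_rate",
    "participant_summary",
    "cohort_summary",
]


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-participant behavioral rates (percentages in [0, 100])."""

    participant_id: int
    ev_max_rate_rich: Optional[float]
    ev_max_rate_poor: Optional[float]
    reversal_rate: Optional[float]
    n_pairs_compared: int
    n_tied_ev_trials: int = 0


def ev_maximization_rate(
    choices: Sequence[ChoiceRecord],
    problems,
    domain: Optional[Domain] = None,
) -> Optional[float]:
    """Percentage of choices of the higher-expected-value option.

    Trials whose two options have exactly equal EV are excluded from the
    denominator; if every trial is tied the rate is undefined (None).
    Invariant to jointly relabeling options A/B in problems and choices.
    """
    idx = index_problems(problems)
    n_max = n_valid = 0
    for rec in choices:
        if domain is not None and rec.domain != domain:
            continue
        prob = idx[(rec.template_id, rec.domain)]
        ev_a = expected_value(prob.option_a)
        ev_b = expected_value(prob.option_b)
        if ev_a == ev_b:
            continue
        better = "A" if ev_a > ev_b else "B"
        n_valid += 1
        n_max += rec.chosen == better
    if n_valid == 0:
        return None
    return 100.0 * n_max / n_valid


def _match_choices(
    choices_rich: Sequence[ChoiceRecord],
    choices_poor: Sequence[ChoiceRecord],
    match_on: str,
) -> list[tuple[str, str]]:
    if match_on == "presentation":
        key = lambda c: (c.participant_id, c.template_id, c.evaluated_option)
    elif match_on == "template":
        key = lambda c: (c.participant_id, c.template_id)
    else:
        raise ValueError("match_on must be 'presentation' or 'template'")
    rich: dict[tuple, list[str]] = {}
    poor: dict[tuple, list[str]] = {}
    for c in choices_rich:
        rich.setdefault(key(c), []).append(c.chosen)
    for c in choices_poor:
        poor.setdefault(key(c), []).append(c.chosen)
    pairs = []
    for k in sorted(set(rich) & set(poor)):
        if match_on == "presentation":
            for a, b in zip(rich[k], poor[k]):
                pairs.append((a, b))
        else:
            maj = lambda v: "A" if v.count("A") * 2 >= len(v) else "B"
            pairs.append((maj(rich[k]), maj(poor[k])))
    return pairs


def preference_reversal_rate(
    choices_rich: Sequence[ChoiceRecord],
    choices_poor: Sequence[ChoiceRecord],
    match_on: str = "presentation",
) -> tuple[Optional[float], int]:
    """Percentage of matched cross-domain pairs with differing choices.

    Pairs are matched on (template_id, evaluated_option) by default —
    up to 84 comparisons per participant with the standard design — or on
    the template-level majority choice with ``match_on='template'``.
    Symmetric in its two arguments.  Returns (rate, n_pairs); the rate is
    None when no pairs match.
    """
    pairs = _match_choices(choices_rich, choices_poor, match_on)
    if not pairs:
        return None, 0
    n_rev = sum(a != b for a, b in pairs)
    return 100.0 * n_rev / len(pairs), len(pairs)


def participant_summary(
    choices: Sequence[ChoiceRecord],
    problems,
    participant_id: int,
    match_on: str = "presentation",
) -> BehaviorSummary:
    """All behavioral rates for one participant."""
    own = [c for c in choices if c.participant_id == participant_id]
    rich = [c for c in own if c.domain is Domain.AFFECT_RICH]
    poor = [c for c in own if c.domain is Domain.AFFECT_POOR]
    idx = index_problems(problems)
    n_tied = sum(
        expected_value(idx[(c.template_id, c.domain)].option_a)
        == expected_value(idx[(c.template_id, c.domain)].option_b)
        for c in own
    )
    rate, n_pairs = preference_reversal_rate(rich, poor, match_on)
    return BehaviorSummary(
        participant_id=participant_id,
        ev_max_rate_rich=ev_maximization_rate(rich, problems, Domain.AFFECT_RICH),
        ev_max_rate_poor=ev_maximization_rate(poor, problems, Domain.AFFECT_POOR),
        reversal_rate=rate,
        n_pairs_compared=n_pairs,
        n_tied_ev_trials=n_tied,
    )


def cohort_summary(summaries: Sequence[BehaviorSummary]) -> pd.DataFrame:
    """Group table: mean, sample SD (n-1), and median of each rate.

    Participants with an undefined rate are excluded from that rate's
    statistics; the excluded count is reported.
    """
    if not summaries:
        raise ValueError("need at least one participant summary")
    rows = []
    for name in ("ev_max_rate_rich", "ev_max_rate_poor", "reversal_rate"):
        vals = np.array([getattr(s, name) for s in summaries if getattr(s, name) is not None])
        rows.append(
            {
                "rate": name,
                "n": len(vals),
                "n_excluded": len(summaries) - len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
                "median": float(np.median(vals)) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("rate")
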