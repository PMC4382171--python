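"""Model-based trial-by-trial regressors and three-column timing files.

For each trial, the fitted domain-specific CPT parameters yield a
subjective value (the transformed loss magnitude) and a decision weight
(the weighted probability of the option's loss) for the option presented
alone in the evaluation phase or chosen in the decision phase.  These are
exported as whitespace-delimited three-column timing files
(onset, duration, weight) — one unmodulated intercept regressor plus one
parametrically modulated file per quantity — for use by a downstream GLM
tool.  Convolution with the hemodynamic response and motion regressors are
the GLM tool's job.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cpt import CPTParams, decision_weights, value_fn
from .fitting import index_problems
from .lotteries import Domain, Lottery
from .synth import Trial

__all__ = [
    "Phase",
    "TrialEvent",
    "trial_decision_weight",
    "trial_subjective_value",
    "build_events",
    "export_timing",
    "simulate_onsets",
]

EVALUATION_DURATION = 4.0  # seconds the single option is displayed


class Phase(str, enum.Enum):
    EVALUATION = "evaluation"
    DECISION = "decision"


@dataclass(frozen=True)
class TrialEvent:
    """One event for the timing files."""

    onset: float  # seconds from run start
    duration: float  # 4 s (evaluation) or the response time (decision)
    phase: Phase
    option: Lottery  # presented (evaluation) or chosen (decision) option
    value: float  # subjective value of the option's loss
    weight: float  # decision weight of the option's loss

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not (np.isfinite(self.value) and np.isfinite(self.weight)):
            raise ValueError("regressor values must be finite")


def trial_decision_weight(option: Lottery, params: CPTParams) -> float:
    """Decision weight of the option's loss outcome.

    The rank-dependent weight of the most severe (most negative) outcome
    under the domain-specific gamma and delta; for a two-branch prospect
    this is ``w(p_loss)``.  Identity parameters reproduce the raw
    probability.
    """
    if params is None:
        raise ValueError("fitted parameters required")
    pi = decision_weights(option, params.gamma, params.delta)
    # after badness sorting the worst outcome is last
    return float(pi[-1])


def trial_subjective_value(option: Lottery, params: CPTParams) -> float:
    """Subjective value of the option's loss magnitude under alpha."""
    if params is None:
        raise ValueError("fitted parameters required")
    x, _ = option.loss_branch()
    return float(value_fn(x, params.alpha))


def simulate_onsets(
    n_trials: int,
    seed: int = 0,
    eval_to_decision_jitter: tuple[float, float] = (2.0, 9.0),
    decision_to_next_jitter: tuple[float, float] = (3.0, 11.0),
    rt_range: tuple[float, float] = (0.8, 4.0),
) -> list[tuple[float, float, float]]:
    """Simulated (evaluation onset, decision onset, response time) per trial.

    Fixation jitter is uniform over the stated ranges: 2-9 s between the
    evaluation and decision phases, 3-11 s between a decision and the next
    trial's evaluation.
    """
    rng = np.random.default_rng(seed)
    out = []
    t = 0.0
    for _ in range(n_trials):
        eval_onset = t
        dec_onset = eval_onset + EVALUATION_DURATION + rng.uniform(*eval_to_decision_jitter)
        rt = rng.uniform(*rt_range)
        out.append((eval_onset, dec_onset, rt))
        t = dec_onset + rt + rng.uniform(*decision_to_next_jitter)
    return out


def build_events(
    trials: Sequence[Trial],
    problems,
    choices=None,
    params_by_domain: Optional[dict[Domain, CPTParams]] = None,
    phase: Phase = Phase.EVALUATION,
    onsets: Optional[Sequence[tuple[float, float, float]]] = None,
    seed: int = 0,
) -> list[TrialEvent]:
    """One TrialEvent per trial.

    Evaluation-phase events use the option presented alone; decision-phase
    events use the chosen option (``choices`` required, matched positionally
    to ``trials``).  ``params_by_domain`` maps each domain to its fitted
    parameters.
    """
    phase = Phase(phase)
    if params_by_domain is None:
        raise ValueError("params_by_domain is required")
    if phase is Phase.DECISION and choices is None:
        raise ValueError("decision-phase events need the choice records")
    idx = index_problems(problems)
    if onsets is None:
        onsets = simulate_onsets(len(trials), seed=seed)
    events = []
    for i, tr in enumerate(trials):
        prob = idx[(tr.template_id, tr.domain)]
        if phase is Phase.EVALUATION:
            option = prob.option(tr.evaluated_option)
            onset, duration = onsets[i][0], EVALUATION_DURATION
        else:
            option = prob.option(choices[i].chosen)
            onset, duration = onsets[i][1], onsets[i][2]
        params = params_by_domain[tr.domain]
        events.append(
            TrialEvent(
                onset=onset,
                duration=duration,
                phase=phase,
                option=option,
                value=trial_subjective_value(option, params),
                weight=trial_decision_weight(option, params),
            )
        )
    return events


def export_timing(
    events: Sequence[TrialEvent],
    out_dir: Union[str, Path],
    prefix: str = "run1",
    mean_center: bool = True,
) -> dict[str, Path]:
    """Write three-column (onset, duration, weight) timing files.

    Three files per call: the unmodulated intercept (weight 1), the
    subjective-value modulator, and the decision-weight modulator.
    Modulated columns are mean-centered per run by default — the
    three-column-file equivalent of orthogonalizing each modulator against
    its intercept regressor.
    """
    if not events:
        raise ValueError("empty event list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    onsets = np.array([e.onset for e in events])
    durations = np.array([e.duration for e in events])
    values = np.array([e.value for e in events])
    weights = np.array([e.weight for e in events])
    if mean_center:
        values = values - values.mean()
        weights = weights - weights.mean()
    paths = {}
    for name, col in (
        ("intercept", np.ones(len(events))),
        ("value", values),
        ("weight", weights),
    ):
        path = out / f"{prefix}_{name}.txt"
        np.savetxt(path, np.column_stack([onsets, durations, col]), fmt="%.6f")
        paths[name] = path
    return paths
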