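"""Synthetic study design and choice simulation.

Emulates the study structure end to end: four side effects ranked by
severity with elicited willingness-to-pay (WTP) amounts, 42 two-branch
loss-lottery problems per domain built from 8 fixed probabilities and
designed for comparable expected values, each problem presented twice with
the evaluated option counterbalanced, trials sequenced in alternating
domain blocks of three, and choices sampled from per-domain CPT parameters
through the softmax-plus-guessing rule.

The affect-poor twin of each affect-rich problem is monetarily identical
(the side effect replaced by the participant's WTP for it); behavioral
differences between domains arise solely from the domain-specific CPT
parameters used to generate choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .cpt import ChoiceRule, CPTParams, softmax_choice_prob
from .estimator import TrialData
from .lotteries import ChoiceRecord, Domain, Lottery, LotteryProblem

__all__ = [
    "SIDE_EFFECTS",
    "DEFAULT_PROBABILITIES",
    "DEFAULT_PILOT_MEDIAN_WTP",
    "PARAM_MEANS",
    "PARAM_SDS",
    "DesignSpec",
    "SimulatedParticipant",
    "ProblemTemplate",
    "Trial",
    "sample_wtp",
    "sample_params",
    "build_templates",
    "build_design",
    "simulate_choices",
    "simulate_cohort",
    "CohortData",
]

SIDE_EFFECTS = ("fatigue", "insomnia", "depression", "memory problems")

DEFAULT_PROBABILITIES = (0.05, 0.08, 0.15, 0.18, 0.5, 0.53, 0.95, 0.98)

# Median WTP by severity rank (1 = most unpleasant) used only to lay out
# EV-comparable problem templates; each participant then sees her own WTPs.
DEFAULT_PILOT_MEDIAN_WTP = {1: 100.0, 2: 60.0, 3: 35.0, 4: 20.0}

# Group-level parameter means and SDs by domain, used as the default
# generating distribution (truncated normal within the CPT bounds).
PARAM_MEANS = {
    Domain.AFFECT_POOR: {"gamma": 0.77, "delta": 0.99, "alpha": 0.73, "g": 0.07},
    Domain.AFFECT_RICH: {"gamma": 0.43, "delta": 2.47, "alpha": 0.79, "g": 0.12},
}
PARAM_SDS = {
    Domain.AFFECT_POOR: {"gamma": 0.24, "delta": 1.63, "alpha": 0.21, "g": 0.11},
    Domain.AFFECT_RICH: {"gamma": 0.33, "delta": 3.10, "alpha": 0.26, "g": 0.19},
}

_PARAM_BOUNDS = {
    "alpha": (1e-6, 1.0),
    "gamma": (1e-6, 1.0),
    "delta": (1e-6, 10.0),
    "g": (1e-6, 1.0),
}


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of the lottery-problem design.

    ``ev_ratio_tolerance`` bounds the expected-value ratio of the paired
    options at template-construction time: ``|log(EV_A / EV_B)| <=
    log(tolerance)`` under the pilot median WTPs.
    """

    probabilities: tuple[float, ...] = DEFAULT_PROBABILITIES
    n_problems: int = 42
    n_presentations: int = 2
    block_size: int = 3
    ev_ratio_tolerance: float = 1.5
    pilot_median_wtp: Optional[dict[int, float]] = None
    seed: int = 0

    def __post_init__(self):
        if any(not (0.0 < p < 1.0) for p in self.probabilities):
            raise ValueError("probabilities must lie in (0, 1)")
        if self.n_presentations != 2:
            raise ValueError("the design presents each problem exactly twice")
        if self.ev_ratio_tolerance <= 1.0:
            raise ValueError("ev_ratio_tolerance must exceed 1")

    @property
    def pilot_wtp(self) -> dict[int, float]:
        return dict(self.pilot_median_wtp or DEFAULT_PILOT_MEDIAN_WTP)


@dataclass(frozen=True)
class ProblemTemplate:
    """Participant-independent skeleton of one lottery problem.

    ``rank_small``/``rank_big`` are severity ranks whose WTPs supply the
    smaller and larger loss magnitude; the smaller loss occurs with the
    higher probability.  ``a_is_small`` fixes which side is option A.
    """

    template_id: int
    rank_small: int
    rank_big: int
    p_high: float
    p_low: float
    a_is_small: bool


@dataclass(frozen=True)
class Trial:
    """One slot in the within-scanner sequence."""

    order: int
    domain: Domain
    template_id: int
    presentation_index: int
    evaluated_option: str


@dataclass(frozen=True)
class SimulatedParticipant:
    """Ground truth for one simulated participant."""

    participant_id: int
    severity_ranking: tuple[str, ...]  # side effects, most to least unpleasant
    wtp: dict[str, float]  # side effect label -> WTP (positive)
    params_rich: CPTParams
    params_poor: CPTParams
    affect_ratings: Optional[dict[str, dict[str, int]]] = None

    @property
    def wtp_by_rank(self) -> dict[int, float]:
        return {r + 1: self.wtp[label] for r, label in enumerate(self.severity_ranking)}

    def params_for(self, domain: Domain) -> CPTParams:
        return self.params_rich if domain is Domain.AFFECT_RICH else self.params_poor


def sample_wtp(
    n_participants: int,
    seed: int,
    median: float = 50.0,
    sigma_log: float = 0.8,
    labels: Sequence[str] = SIDE_EFFECTS,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[tuple[str, ...], dict[str, float]]]:
    """Sample severity rankings and WTPs for ``n_participants``.

    WTPs are log-normal (median ``median``, log-scale SD ``sigma_log``) and
    sorted so the amount is monotone in the participant's severity ranking
    (most unpleasant side effect gets the largest WTP).  Returns
    ``(ranking, wtp_map)`` per participant.
    """
    if len(labels) != 4:
        raise ValueError("the design uses exactly 4 side effects")
    if median <= 0 or sigma_log <= 0:
        raise ValueError("median and sigma_log must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = []
    for _ in range(n_participants):
        ranking = tuple(rng.permutation(list(labels)))
        # kept unrounded: strict ordering guarantees distinct magnitudes in
        # every instantiated problem pair
        draws = np.sort(rng.lognormal(np.log(median), sigma_log, size=4))[::-1]
        wtp = {label: float(v) for label, v in zip(ranking, draws)}
        out.append((ranking, wtp))
    return out


def sample_params(
    domain: Domain,
    rng: np.random.Generator,
    means: Optional[dict[str, float]] = None,
    sds: Optional[dict[str, float]] = None,
) -> CPTParams:
    """Draw CPT parameters from a truncated normal within the model bounds."""
    means = means or PARAM_MEANS[domain]
    sds = sds or PARAM_SDS[domain]
    vals = {}
    for name in ("alpha", "gamma", "delta", "g"):
        lo, hi = _PARAM_BOUNDS[name]
        mu, sd = means[name], sds[name]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        vals[name] = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
    return CPTParams(**vals)


def build_templates(spec: DesignSpec) -> list[ProblemTemplate]:
    """Construct the EV-comparable problem templates.

    Candidate pairings of (severity-rank pair, probability pair) are ranked
    by |log EV ratio| under the pilot median WTPs.  Selection first covers
    every probability in the design (each probability's best candidate),
    then fills remaining slots by global rank.  If the tolerance admits
    fewer than ``n_problems`` candidates it is relaxed with a warning.
    """
    pilot = spec.pilot_wtp
    probs = sorted(spec.probabilities)
    ranks = sorted(pilot)
    candidates = []  # (|log ev ratio|, enumeration order, fields)
    order = 0
    for r_big in ranks:
        for r_small in ranks:
            if pilot[r_small] >= pilot[r_big]:
                continue
            for i, p_low in enumerate(probs):
                for p_high in probs[i + 1:]:
                    ev_small = pilot[r_small] * p_high
                    ev_big = pilot[r_big] * p_low
                    dev = abs(np.log(ev_small / ev_big))
                    candidates.append((dev, order, (r_small, r_big, p_high, p_low)))
                    order += 1
    candidates.sort(key=lambda c: (c[0], c[1]))
    max_dev = np.log(spec.ev_ratio_tolerance)
    within = [c for c in candidates if c[0] <= max_dev]
    if len(within) < spec.n_problems:
        warnings.warn(
            f"EV tolerance {spec.ev_ratio_tolerance} admits only {len(within)} "
            f"of {spec.n_problems} problems; relaxing to fill the design"
        )
        within = candidates[: spec.n_problems]

    chosen: list[tuple[float, int, tuple]] = []
    chosen_keys: set[int] = set()
    # coverage pass: best candidate containing each design probability
    for p in probs:
        for cand in within:
            _, key, (_, _, p_hi, p_lo) = cand
            if key in chosen_keys:
                continue
            if p in (p_hi, p_lo):
                chosen.append(cand)
                chosen_keys.add(key)
                break
    for cand in within:
        if len(chosen) >= spec.n_problems:
            break
        if cand[1] not in chosen_keys:
            chosen.append(cand)
            chosen_keys.add(cand[1])
    if len(chosen) < spec.n_problems:
        raise ValueError("candidate pool too small for the requested problem count")
    chosen.sort(key=lambda c: c[1])
    templates = []
    for tid, (_, _, (r_small, r_big, p_high, p_low)) in enumerate(chosen, start=1):
        templates.append(
            ProblemTemplate(
                template_id=tid,
                rank_small=r_small,
                rank_big=r_big,
                p_high=p_high,
                p_low=p_low,
                a_is_small=(tid % 2 == 1),  # balanced, deterministic side assignment
            )
        )
    return templates


def _instantiate(template: ProblemTemplate, wtp_by_rank: dict[int, float],
                 rank_labels: dict[int, str], domain: Domain) -> LotteryProblem:
    x_small = -wtp_by_rank[template.rank_small]
    x_big = -wtp_by_rank[template.rank_big]
    small = Lottery([0.0, x_small], [1.0 - template.p_high, template.p_high])
    big = Lottery([0.0, x_big], [1.0 - template.p_low, template.p_low])
    lab_small = rank_labels[template.rank_small]
    lab_big = rank_labels[template.rank_big]
    if template.a_is_small:
        a, b, labels = small, big, (lab_small, lab_big)
    else:
        a, b, labels = big, small, (lab_big, lab_small)
    return LotteryProblem(
        template_id=template.template_id,
        domain=domain,
        option_a=a,
        option_b=b,
        side_effect_labels=labels if domain is Domain.AFFECT_RICH else None,
    )


def build_design(
    spec: DesignSpec,
    wtp_by_rank: dict[int, float],
    rank_labels: Optional[dict[int, str]] = None,
    seed: Optional[int] = None,
    templates: Optional[list[ProblemTemplate]] = None,
) -> tuple[list[LotteryProblem], list[Trial]]:
    """Instantiate both domains' problems for one participant plus the
    trial sequence.

    Twin problems share template id and probabilities; the affect-poor twin
    replaces the side-effect labels with the same monetary magnitudes (the
    participant's WTPs).  The sequence alternates domain blocks of
    ``block_size`` trials; within each domain the 84 (problem, evaluated
    option) slots are shuffled by the seed, with each option of each problem
    evaluated exactly once.
    """
    if templates is None:
        templates = build_templates(spec)
    if rank_labels is None:
        rank_labels = {r: f"rank{r}" for r in wtp_by_rank}
    monotone = all(
        wtp_by_rank[r] >= wtp_by_rank[r + 1] for r in sorted(wtp_by_rank)[:-1]
    )
    if not monotone:
        raise ValueError("WTP must be monotone in severity rank (rank 1 largest)")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    problems = [
        _instantiate(t, wtp_by_rank, rank_labels, domain)
        for domain in (Domain.AFFECT_RICH, Domain.AFFECT_POOR)
        for t in templates
    ]

    trials: list[Trial] = []
    per_domain: dict[Domain, list[tuple[int, str]]] = {}
    for domain in (Domain.AFFECT_RICH, Domain.AFFECT_POOR):
        slots = []
        for t in templates:
            first_a = bool(rng.integers(2))
            slots.append((t.template_id, "A" if first_a else "B"))
            slots.append((t.template_id, "B" if first_a else "A"))
        perm = rng.permutation(len(slots))
        per_domain[domain] = [slots[i] for i in perm]

    first = Domain.AFFECT_RICH if rng.integers(2) else Domain.AFFECT_POOR
    second = Domain.AFFECT_POOR if first is Domain.AFFECT_RICH else Domain.AFFECT_RICH
    n_per_domain = spec.n_problems * spec.n_presentations
    seen: dict[tuple[Domain, int], int] = {}
    order = 0
    pos = {first: 0, second: 0}
    for block in range(int(np.ceil(2 * n_per_domain / spec.block_size / 2)) * 2):
        domain = first if block % 2 == 0 else second
        for _ in range(spec.block_size):
            if pos[domain] >= n_per_domain:
                break
            tid, ev_opt = per_domain[domain][pos[domain]]
            pos[domain] += 1
            seen[(domain, tid)] = seen.get((domain, tid), 0) + 1
            trials.append(
                Trial(
                    order=order,
                    domain=domain,
                    template_id=tid,
                    presentation_index=seen[(domain, tid)],
                    evaluated_option=ev_opt,
                )
            )
            order += 1
    return problems, trials


def simulate_choices(
    participant: SimulatedParticipant,
    trials: Sequence[Trial],
    problems: Sequence[LotteryProblem],
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list[ChoiceRecord]:
    """Sample one choice per trial from the CPT choice rule.

    Each choice is Bernoulli with probability ``choice_prob(A, B)`` under
    the participant's domain-specific parameters; reproducible by seed.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = {(p.template_id, p.domain): p for p in problems}
    rule = ChoiceRule(rule)
    records = []
    by_domain: dict[Domain, list[int]] = {}
    for i, tr in enumerate(trials):
        by_domain.setdefault(tr.domain, []).append(i)
    p_a_all = np.empty(len(trials))
    for domain, rows in by_domain.items():
        params = participant.params_for(domain)
        X = []
        for i in rows:
            prob = idx[(trials[i].template_id, domain)]
            X.append((*prob.option_a.loss_branch(), *prob.option_b.loss_branch()))
        data = TrialData(np.zeros(len(rows), dtype=bool), X=np.asarray(X))
        va, vb = data.valuations(params.alpha, params.gamma, params.delta)
        if rule is ChoiceRule.GUESS_ONLY:
            p_a = softmax_choice_prob(va, vb, g=params.g, phi=1.0)
        elif rule is ChoiceRule.SENSITIVITY_ONLY:
            p_a = softmax_choice_prob(va, vb, g=0.0, phi=params.phi)
        else:
            p_a = softmax_choice_prob(va, vb, g=params.g, phi=params.phi)
        p_a_all[rows] = p_a
    draws = rng.random(len(trials))
    for tr, p_a, u in zip(trials, p_a_all, draws):
        records.append(
            ChoiceRecord(
                participant_id=participant.participant_id,
                template_id=tr.template_id,
                domain=tr.domain,
                presentation_index=tr.presentation_index,
                evaluated_option=tr.evaluated_option,
                chosen="A" if u < p_a else "B",
            )
        )
    return records


@dataclass
class CohortData:
    """A fully simulated cohort."""

    spec: DesignSpec
    participants: list[SimulatedParticipant]
    problems: dict[int, list[LotteryProblem]]  # participant_id -> problems
    trials: dict[int, list[Trial]]
    choices: list[ChoiceRecord]

    def choices_for(self, participant_id: int, domain: Optional[Domain] = None):
        return [
            c
            for c in self.choices
            if c.participant_id == participant_id
            and (domain is None or c.domain == domain)
        ]


def _affect_ratings(wtp: dict[str, float], rng: np.random.Generator) -> dict[str, dict[str, int]]:
    # 1-10 upset ratings; side effects rated stochastically >= matched losses
    # (schema completeness only).
    order = sorted(wtp, key=wtp.get)
    ratings = {"side_effect": {}, "monetary_loss": {}}
    for i, label in enumerate(order):
        base = 3 + 2 * i + rng.integers(-1, 2)
        loss = int(np.clip(base - rng.integers(0, 3), 1, 10))
        se = int(np.clip(loss + rng.integers(0, 4), 1, 10))
        ratings["monetary_loss"][label] = loss
        ratings["side_effect"][label] = se
    return ratings


def simulate_cohort(
    n_participants: int = 23,
    spec: Optional[DesignSpec] = None,
    param_means: Optional[dict[Domain, dict[str, float]]] = None,
    param_sds: Optional[dict[Domain, dict[str, float]]] = None,
    rule: ChoiceRule = ChoiceRule.GUESS_ONLY,
    seed: int = 0,
    wtp_median: float = 50.0,
    wtp_sigma_log: float = 0.8,
) -> CohortData:
    """Simulate a full cohort: WTPs, designs, parameters, and choices.

    Parameters are drawn per participant and domain from truncated normals
    around the group-level means/SDs (defaults above).  With the default
    spec each participant contributes 84 affect-rich and 84 affect-poor
    choice records.
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(seed)
    templates = build_templates(spec)
    wtps = sample_wtp(n_participants, seed=0, median=wtp_median,
                      sigma_log=wtp_sigma_log, rng=rng)
    participants, problems, trials, choices = [], {}, {}, []
    for pid in range(1, n_participants + 1):
        ranking, wtp = wtps[pid - 1]
        p_rich = sample_params(Domain.AFFECT_RICH, rng, (param_means or PARAM_MEANS)[Domain.AFFECT_RICH],
                               (param_sds or PARAM_SDS)[Domain.AFFECT_RICH])
        p_poor = sample_params(Domain.AFFECT_POOR, rng, (param_means or PARAM_MEANS)[Domain.AFFECT_POOR],
                               (param_sds or PARAM_SDS)[Domain.AFFECT_POOR])
        part = SimulatedParticipant(
            participant_id=pid,
            severity_ranking=ranking,
            wtp=wtp,
            params_rich=p_rich,
            params_poor=p_poor,
            affect_ratings=_affect_ratings(wtp, rng),
        )
        rank_labels = {r + 1: label for r, label in enumerate(ranking)}
        probs, seq = build_design(
            spec, part.wtp_by_rank, rank_labels,
            seed=int(rng.integers(2**31 - 1)), templates=templates,
        )
        recs = simulate_choices(part, seq, probs, rule=rule, rng=rng)
        participants.append(part)
        problems[pid] = probs
        trials[pid] = seq
        choices.extend(recs)
    return CohortData(spec=spec, participants=participants, problems=problems,
                      trials=trials, choices=choices)
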