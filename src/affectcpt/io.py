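"""Delimited-text I/O for problem sets, choice data, and fit results.

Problems CSV columns: participant_id, template_id, domain, outcome_a,
prob_a, outcome_b, prob_b, label_a, label_b.  Each row encodes one
two-branch problem: option A loses ``outcome_a`` (<= 0) with probability
``prob_a`` and nothing otherwise, likewise option B.  Labels are the side
effects of affect-rich problems (blank for affect-poor).

Choices CSV columns: participant_id, template_id, domain,
presentation_index, evaluated_option, chosen.

The readers validate the type invariants and report row-level errors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cpt import CPTParams
from .lotteries import ChoiceRecord, Domain, Lottery, LotteryProblem
from .synth import CohortData, SimulatedParticipant

__all__ = [
    "write_problems_csv",
    "read_problems_csv",
    "write_choices_csv",
    "read_choices_csv",
    "write_participants_json",
    "read_participants_json",
    "write_cohort",
]

PROBLEM_COLUMNS = [
    "participant_id", "template_id", "domain",
    "outcome_a", "prob_a", "outcome_b", "prob_b", "label_a", "label_b",
]
CHOICE_COLUMNS = [
    "participant_id", "template_id", "domain",
    "presentation_index", "evaluated_option", "chosen",
]

PathLike = Union[str, Path]


def problems_to_frame(problems: dict[int, Sequence[LotteryProblem]]) -> pd.DataFrame:
    rows = []
    for pid, probs in problems.items():
        for p in probs:
            xa, pa = p.option_a.loss_branch()
            xb, pb = p.option_b.loss_branch()
            la, lb = p.side_effect_labels or ("", "")
            rows.append((pid, p.template_id, p.domain.value, xa, pa, xb, pb, la, lb))
    return pd.DataFrame(rows, columns=PROBLEM_COLUMNS)


def write_problems_csv(problems: dict[int, Sequence[LotteryProblem]], path: PathLike) -> None:
    problems_to_frame(problems).to_csv(path, index=False)


def _two_branch(x: float, p: float) -> Lottery:
    if p == 1.0:
        return Lottery([x], [1.0])
    return Lottery([0.0, x], [1.0 - p, p])


def read_problems_csv(path: PathLike) -> dict[int, list[LotteryProblem]]:
    """Read a problem set; returns participant_id -> problems.

    Row-level violations (positive outcomes, probabilities outside (0, 1],
    malformed pairs) are collected and raised together.
    """
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(PROBLEM_COLUMNS) - {"participant_id", "label_a", "label_b"} - set(df.columns)
    if missing:
        raise ValueError(f"problems CSV missing columns: {sorted(missing)}")
    if "participant_id" not in df.columns:
        df["participant_id"] = 0
    out: dict[int, list[LotteryProblem]] = {}
    errors = []
    for i, row in df.iterrows():
        try:
            labels = None
            if row.get("label_a", "") or row.get("label_b", ""):
                labels = (str(row["label_a"]), str(row["label_b"]))
            prob = LotteryProblem(
                template_id=int(row["template_id"]),
                domain=Domain(row["domain"]),
                option_a=_two_branch(float(row["outcome_a"]), float(row["prob_a"])),
                option_b=_two_branch(float(row["outcome_b"]), float(row["prob_b"])),
                side_effect_labels=labels,
            )
            out.setdefault(int(row["participant_id"]), []).append(prob)
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("invalid problems CSV:\n" + "\n".join(errors))
    return out


def choices_to_frame(choices: Sequence[ChoiceRecord]) -> pd.DataFrame:
    rows = [
        (c.participant_id, c.template_id, c.domain.value,
         c.presentation_index, c.evaluated_option, c.chosen)
        for c in choices
    ]
    return pd.DataFrame(rows, columns=CHOICE_COLUMNS)


def write_choices_csv(choices: Sequence[ChoiceRecord], path: PathLike) -> None:
    choices_to_frame(choices).to_csv(path, index=False)


def read_choices_csv(path: PathLike, validate: bool = True) -> list[ChoiceRecord]:
    """Read choice records, validating per-row fields and the pairing
    invariant: each (participant, template, domain) appears exactly twice,
    once per evaluated option.
    """
    df = pd.read_csv(path)
    missing = set(CHOICE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"choices CSV missing columns: {sorted(missing)}")
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            records.append(
                ChoiceRecord(
                    participant_id=int(row["participant_id"]),
                    template_id=int(row["template_id"]),
                    domain=Domain(row["domain"]),
                    presentation_index=int(row["presentation_index"]),
                    evaluated_option=str(row["evaluated_option"]),
                    chosen=str(row["chosen"]),
                )
            )
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if validate and not errors:
        grouped: dict[tuple, list[str]] = {}
        for rec in records:
            grouped.setdefault(
                (rec.participant_id, rec.template_id, rec.domain), []
            ).append(rec.evaluated_option)
        for key, evs in grouped.items():
            if sorted(evs) != ["A", "B"]:
                errors.append(
                    f"participant {key[0]} template {key[1]} {key[2].value}: "
                    f"expected two presentations with distinct evaluated options, got {evs}"
                )
    if errors:
        raise ValueError("invalid choices CSV:\n" + "\n".join(errors))
    return records


def _params_dict(p: CPTParams) -> dict:
    return {"alpha": p.alpha, "gamma": p.gamma, "delta": p.delta, "g": p.g, "phi": p.phi}


def write_participants_json(participants: Sequence[SimulatedParticipant], path: PathLike) -> None:
    """Ground-truth parameters and WTPs, for parameter-recovery scoring."""
    payload = [
        {
            "participant_id": p.participant_id,
            "severity_ranking": list(p.severity_ranking),
            "wtp": p.wtp,
            "params_rich": _params_dict(p.params_rich),
            "params_poor": _params_dict(p.params_poor),
            "affect_ratings": p.affect_ratings,
        }
        for p in participants
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_participants_json(path: PathLike) -> list[SimulatedParticipant]:
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload:
        out.append(
            SimulatedParticipant(
                participant_id=entry["participant_id"],
                severity_ranking=tuple(entry["severity_ranking"]),
                wtp=entry["wtp"],
                params_rich=CPTParams(**entry["params_rich"]),
                params_poor=CPTParams(**entry["params_poor"]),
                affect_ratings=entry.get("affect_ratings"),
            )
        )
    return out


def write_cohort(cohort: CohortData, out_dir: PathLike) -> dict[str, Path]:
    """Write a simulated cohort as problems.csv, choices.csv, participants.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "problems": out / "problems.csv",
        "choices": out / "choices.csv",
        "participants": out / "participants.json",
    }
    write_problems_csv(cohort.problems, paths["problems"])
    write_choices_csv(cohort.choices, paths["choices"])
    write_participants_json(cohort.participants, paths["participants"])
    return paths
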