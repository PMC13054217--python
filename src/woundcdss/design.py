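"""AB/BA crossover bookkeeping: block randomization and table assembly.

The evaluation study is a two-period, two-sequence crossover: sequence A
receives the decision-support intervention in period 1 (questions 1-5)
and control in period 2 (questions 6-10); sequence B the reverse.  A
washout of at least one week separates the periods.  The unit of
analysis is the individual question response, so a complete study with
28 clinicians yields a 280-row long-format table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrialDesign", "DEFAULT_DESIGN", "block_randomize", "assemble_long"]

OUTCOME_COLUMNS = ("outcome_total", "outcome_ointment", "outcome_dressing")

TABLE_COLUMNS = (
    "participant_id",
    "sequence",
    "period",
    "treatment",
    "question",
    *OUTCOME_COLUMNS,
)


@dataclass(frozen=True)
class TrialDesign:
    """Sequences, question sets and washout of the crossover."""

    sequences: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "A": ("intervention", "control"),
            "B": ("control", "intervention"),
        }
    )
    question_sets: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {1: tuple(range(1, 6)), 2: tuple(range(6, 11))}
    )
    washout_days: int = 7

    def __post_init__(self) -> None:
        if self.washout_days < 7:
            raise ValueError("washout must be at least 7 days")
        qs = sorted(q for qset in self.question_sets.values() for q in qset)
        if qs != list(range(1, 11)):
            raise ValueError("question sets must partition questions 1-10")

    def treatment_for(self, sequence: str, period: int) -> str:
        return self.sequences[sequence][period - 1]

    def period_for(self, question: int) -> int:
        for period, qset in self.question_sets.items():
            if question in qset:
                return period
        raise KeyError(f"question {question!r} not in any period's set")


DEFAULT_DESIGN = TrialDesign()


def block_randomize(
    participant_ids: Sequence[str], block_size: int = 4, seed: int = 0
) -> dict[str, str]:
    """Permuted-block 1:1 allocation of participants to sequences A and B.

    Within every complete block exactly half go to each arm; the final,
    possibly incomplete block is a truncated random permutation of a
    balanced block.  Reproducible for a fixed seed.
    """
    if block_size % 2 != 0 or block_size < 2:
        raise ValueError("block_size must be an even integer >= 2")
    rng = np.random.default_rng(seed)
    allocation: dict[str, str] = {}
    ids = list(participant_ids)
    for start in range(0, len(ids), block_size):
        block = ["A"] * (block_size // 2) + ["B"] * (block_size // 2)
        rng.shuffle(block)
        for pid, arm in zip(ids[start : start + block_size], block):
            allocation[str(pid)] = arm
    return allocation


def assemble_long(
    allocation: Mapping[str, str],
    responses: pd.DataFrame,
    design: TrialDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Build the analysis table: one row per (participant, question).

    ``responses`` must hold scored responses (columns ``participant_id``,
    ``question`` and the three 0/1 outcome columns); every allocated
    participant must have exactly one response to each of questions
    1-10.  The result adds the design covariates — sequence, period
    (derived from the question set) and treatment (derived from sequence
    and period) — giving participants x 10 rows.
    """
    required = {"participant_id", "question", *OUTCOME_COLUMNS}
    missing_cols = required - set(responses.columns)
    if missing_cols:
        raise ValueError(f"responses lack column(s): {sorted(missing_cols)}")
    responses = responses.copy()
    responses["participant_id"] = responses["participant_id"].astype(str)
    responses["question"] = responses["question"].astype(int)

    all_questions = sorted(q for qs in design.question_sets.values() for q in qs)
    have = set(zip(responses["participant_id"], responses["question"]))
    gaps = [
        (pid, q)
        for pid in allocation
        for q in all_questions
        if (str(pid), q) not in have
    ]
    if gaps:
        raise ValueError(f"missing (participant, question) responses: {gaps}")
    dupes = responses.duplicated(subset=["participant_id", "question"])
    if dupes.any():
        raise ValueError("duplicate (participant, question) responses")
    extra = set(responses["participant_id"]) - {str(p) for p in allocation}
    if extra:
        raise ValueError(f"responses from unallocated participant(s): {sorted(extra)}")

    table = responses.copy()
    table["sequence"] = table["participant_id"].map({str(k): v for k, v in allocation.items()})
    table["period"] = table["question"].map(design.period_for)
    table["treatment"] = [
        design.treatment_for(s, p) for s, p in zip(table["sequence"], table["period"])
    ]
    table = table[list(TABLE_COLUMNS)]
    return table.sort_values(["participant_id", "question"]).reset_index(drop=True)
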