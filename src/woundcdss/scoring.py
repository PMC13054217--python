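"""Strict scoring of clinician responses against the 10-question answer key.

Each of the ten evaluation scenarios has exactly one "most appropriate"
ointment option and one "most appropriate" dressing option; scoring is
exact match on each component with no partial credit (notably, question 4
accepts only the plain povidone-iodine option for the ointment even
though silver sulfadiazine appears plausible).  ``both_correct`` is the
product of the two component scores and is the primary outcome of the
evaluation study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "AnswerKey",
    "ScoredResponse",
    "load_default_key",
    "load_question_states",
    "score_response",
    "score_table",
    "phase_rates",
]


@dataclass(frozen=True)
class AnswerKey:
    """Question id (1-10) -> (correct ointment code, correct dressing code)."""

    entries: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.entries) != set(range(1, 11)):
            raise ValueError("answer key must cover exactly questions 1-10")
        for q, (o, d) in self.entries.items():
            if not (1 <= o <= 6 and 1 <= d <= 6):
                raise ValueError(f"question {q}: option codes must be in 1-6")
        if self.entries[4][0] != 4:
            raise ValueError(
                "question 4 ointment must be code 4 (strict povidone-iodine rule)"
            )

    @classmethod
    def from_json(cls, text: str) -> "AnswerKey":
        doc = json.loads(text)
        entries = {
            int(q): (int(v["ointment"]), int(v["dressing"]))
            for q, v in doc["entries"].items()
        }
        return cls(entries=entries)


def load_default_key() -> AnswerKey:
    text = (resources.files("woundcdss") / "data" / "answer_key.json").read_text()
    return AnswerKey.from_json(text)


def load_question_states() -> dict[int, dict]:
    """The structured wound states encoding the ten photograph scenarios.

    Returns ``{question id: {"description": str, "state": field mapping}}``.
    """
    text = (resources.files("woundcdss") / "data" / "question_states.json").read_text()
    doc = json.loads(text)
    return {int(q): v for q, v in doc["states"].items()}


@dataclass(frozen=True)
class ScoredResponse:
    ointment_correct: int
    dressing_correct: int

    @property
    def both_correct(self) -> int:
        return self.ointment_correct * self.dressing_correct


def score_response(
    question: int, ointment: int, dressing: int, key: Optional[AnswerKey] = None
) -> ScoredResponse:
    """Exact-match score of one response against the key."""
    if key is None:
        key = load_default_key()
    if question not in key.entries:
        raise KeyError(f"unknown question id: {question!r}")
    if not (1 <= int(ointment) <= 6 and 1 <= int(dressing) <= 6):
        raise ValueError("option codes must be in 1-6")
    correct_o, correct_d = key.entries[question]
    return ScoredResponse(
        ointment_correct=int(int(ointment) == correct_o),
        dressing_correct=int(int(dressing) == correct_d),
    )


def score_table(responses: pd.DataFrame, key: Optional[AnswerKey] = None) -> pd.DataFrame:
    """Score a long-format response table.

    Expects columns ``question``, ``ointment_code``, ``dressing_code``;
    returns a copy with ``outcome_ointment``, ``outcome_dressing`` and
    ``outcome_total`` (0/1) columns appended.
    """
    if key is None:
        key = load_default_key()
    required = {"question", "ointment_code", "dressing_code"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"response table lacks column(s): {sorted(missing)}")
    out = responses.copy()
    scored = [
        score_response(int(q), int(o), int(d), key)
        for q, o, d in zip(out["question"], out["ointment_code"], out["dressing_code"])
    ]
    out["outcome_ointment"] = [s.ointment_correct for s in scored]
    out["outcome_dressing"] = [s.dressing_correct for s in scored]
    out["outcome_total"] = [s.both_correct for s in scored]
    return out


def phase_rates(scored: pd.DataFrame) -> pd.DataFrame:
    """Raw correct-response proportions per treatment phase.

    One row per phase with total/ointment/dressing rates (percent), the
    denominator, and a count of missing responses excluded from it.
    Model-based (adjusted) estimates are the business of the GEE module;
    these are plain arithmetic means of the 0/1 scores.
    """
    required = {"treatment", "outcome_total", "outcome_ointment", "outcome_dressing"}
    missing_cols = required - set(scored.columns)
    if missing_cols:
        raise ValueError(f"scored table lacks column(s): {sorted(missing_cols)}")
    rows = []
    for phase in ("intervention", "control"):
        sub = scored[scored["treatment"] == phase]
        if len(sub) == 0:
            raise ValueError(f"no responses in phase {phase!r}")
        n_missing = int(
            sub[["outcome_total", "outcome_ointment", "outcome_dressing"]]
            .isna()
            .any(axis=1)
            .sum()
        )
        sub = sub.dropna(subset=["outcome_total", "outcome_ointment", "outcome_dressing"])
        if len(sub) == 0:
            raise ValueError(f"all responses missing in phase {phase!r}")
        rows.append(
            {
                "treatment": phase,
                "total_rate": 100.0 * sub["outcome_total"].mean(),
                "ointment_rate": 100.0 * sub["outcome_ointment"].mean(),
                "dressing_rate": 100.0 * sub["outcome_dressing"].mean(),
                "n": len(sub),
                "n_missing": n_missing,
            }
        )
    return pd.DataFrame(rows).set_index("treatment")
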