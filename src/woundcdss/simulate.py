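"""Synthetic clinician-response generator for the crossover evaluation.

Emulates a panel of clinicians answering the ten wound-treatment
questions across the two crossover periods.  Within-clinician
correlation is induced by a conditional random-intercept logistic model:
participant i answers question q correctly with probability

    expit( logit(p_phase) + u_i + beta_period * 1[period 2]
           + beta_sequence * 1[sequence B] ),   u_i ~ N(0, sd^2)

where ``p_phase`` is the conditional correct-answer probability in the
control or intervention phase.  The ointment and dressing components are
generated as separate binary streams (independent intercepts by
default; a shared-intercept flag couples them), and the primary outcome
is their product.

Because a GEE estimates the population-averaged effect, the quantity it
recovers is not the conditional log-odds difference but its attenuated
marginal counterpart; :func:`marginalize` computes that estimand by
Gauss-Hermite quadrature over the intercept distribution so simulation
studies can test recovery against the correct target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logit, roots_hermitenorm

from .design import DEFAULT_DESIGN, TABLE_COLUMNS, TrialDesign, block_randomize

__all__ = ["SimulationParams", "MarginalSummary", "simulate_trial", "marginalize"]


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of one simulated trial.

    ``p_correct_control`` / ``p_correct_intervention`` are conditional
    (given the clinician's random intercept) per-component probabilities
    of a correct answer; ``random_intercept_sd`` is on the logit scale;
    ``period_effect`` and ``sequence_effect`` are log-odds shifts for
    period 2 and sequence B.  Defaults mirror the pilot study scale:
    28 clinicians and the printed phase rates (4.3% control, 49.3%
    intervention) as anchor probabilities.
    """

    n_participants: int = 28
    p_correct_control: float = 0.043
    p_correct_intervention: float = 0.493
    random_intercept_sd: float = 1.0
    period_effect: float = 0.0
    sequence_effect: float = 0.0
    shared_intercept: bool = False
    block_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_correct_control", "p_correct_intervention"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if self.n_participants < 2 or self.n_participants % 2:
            raise ValueError("n_participants must be an even integer >= 2")


def simulate_trial(
    params: SimulationParams,
    design: TrialDesign = DEFAULT_DESIGN,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate one complete crossover trial; returns the analysis table.

    Participants are allocated to sequences by block randomization, then
    each (participant, question) response is drawn from the conditional
    model above.  Output has the standard long-format columns (one row
    per participant x question, ``outcome_total`` = ointment x dressing).
    Byte-identical for a fixed seed; ``seed`` overrides ``params.seed``.
    """
    rng_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(rng_seed)
    ids = [f"P{i + 1:03d}" for i in range(params.n_participants)]
    allocation = block_randomize(
        ids, block_size=params.block_size, seed=int(rng.integers(2**31 - 1))
    )

    base = {
        "control": logit(params.p_correct_control),
        "intervention": logit(params.p_correct_intervention),
    }
    components = ("ointment", "dressing")
    if params.shared_intercept:
        u_shared = rng.normal(0.0, params.random_intercept_sd, params.n_participants)
        intercepts = {c: u_shared for c in components}
    else:
        intercepts = {
            c: rng.normal(0.0, params.random_intercept_sd, params.n_participants)
            for c in components
        }

    rows = []
    questions = sorted(q for qs in design.question_sets.values() for q in qs)
    for i, pid in enumerate(ids):
        seq = allocation[pid]
        for q in questions:
            period = design.period_for(q)
            treatment = design.treatment_for(seq, period)
            eta_fixed = (
                base[treatment]
                + params.period_effect * (period == 2)
                + params.sequence_effect * (seq == "B")
            )
            draws = {}
            for c in components:
                p = _expit(eta_fixed + intercepts[c][i])
                draws[c] = int(rng.random() < p)
            rows.append(
                {
                    "participant_id": pid,
                    "sequence": seq,
                    "period": period,
                    "treatment": treatment,
                    "question": q,
                    "outcome_total": draws["ointment"] * draws["dressing"],
                    "outcome_ointment": draws["ointment"],
                    "outcome_dressing": draws["dressing"],
                }
            )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass(frozen=True)
class MarginalSummary:
    """Population-averaged per-phase probabilities and treatment log-OR."""

    p_control: float
    p_intervention: float
    log_or: float


def marginalize(params: SimulationParams, n_nodes: int = 80) -> MarginalSummary:
    """Marginal (population-averaged) probabilities implied by ``params``.

    Integrates ``expit(logit(p_phase) + sd * u)`` over the standard
    normal intercept distribution with Gauss-Hermite quadrature,
    evaluated at the reference design cell (period 1, sequence A, where
    the period/sequence shifts are zero).  The returned ``log_or`` is
    the marginal treatment contrast — the estimand a GEE with this
    outcome recovers.
    """
    nodes, weights = roots_hermitenorm(n_nodes)
    weights = weights / weights.sum()  # normalize against the N(0,1) kernel
    if not np.all(np.isfinite(nodes)):
        raise RuntimeError("quadrature failure: non-finite nodes")

    def marginal(p: float) -> float:
        eta = logit(p) + params.random_intercept_sd * nodes
        val = float(np.sum(weights * _expit(eta)))
        if not np.isfinite(val) or not 0.0 < val < 1.0:
            raise RuntimeError("quadrature failure computing marginal probability")
        return val

    p_c = marginal(params.p_correct_control)
    p_i = marginal(params.p_correct_intervention)
    return MarginalSummary(
        p_control=p_c,
        p_intervention=p_i,
        log_or=float(logit(p_i) - logit(p_c)),
    )
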