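"""Deterministic Markov cohort engine for the four-state model.

Per cycle (one year), a row-stochastic 4x4 transition matrix is built
from the arm's annual probabilities and the age-banded background
mortality, and the cohort occupancy vector is propagated through it.
Permitted transitions are one-way: disease-free -> {local recurrence,
metastasis, death}, local recurrence -> {metastasis, death},
metastasis -> death; death is absorbing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conventions import ADDITIVE, ALIVE_STATES, HealthState, ModelConventions
from .params import ArmParameters, ModelConfig, MortalityTable

__all__ = [
    "CohortTrace",
    "InfeasibleProbabilityError",
    "build_transition_matrix",
    "run_cohort",
]

_N = len(HealthState)


class InfeasibleProbabilityError(ValueError):
    """Competing outgoing probabilities sum above 1 for some state/cycle."""


def _death_prob(p_bc: float, p_ac: float, state: HealthState,
                conventions: ModelConventions) -> float:
    bc = p_bc if state in conventions.bc_death_source_states else 0.0
    if conventions.death_combination == ADDITIVE:
        return bc + p_ac
    return 1.0 - (1.0 - bc) * (1.0 - p_ac)


def build_transition_matrix(
    arm: ArmParameters,
    mortality: MortalityTable,
    config: ModelConfig,
    cycle: int,
) -> np.ndarray:
    """Row-stochastic transition matrix for one model cycle (1-based year).

    Cohort age during cycle t is ``start_age + t - 1`` (entry at exactly
    ``start_age``), which determines the background-mortality band.
    Competing transition probabilities within a row are combined
    additively, with the stay probability as the remainder.
    """
    if not 1 <= cycle <= config.horizon:
        raise ValueError(f"cycle must be in 1..{config.horizon}, got {cycle}")
    age = config.start_age + cycle - 1
    p_ac = mortality.annual_probability(age)
    p_bc = arm.p_bc_death[cycle - 1]
    conv = config.conventions

    m = np.zeros((_N, _N))
    df, lr, met, dead = HealthState
    m[df, lr] = arm.p_local_recurrence[cycle - 1]
    m[df, met] = arm.p_metastasis_from_disease_free
    m[df, dead] = _death_prob(p_bc, p_ac, df, conv)
    m[lr, met] = arm.p_metastasis_from_local_recurrence
    m[lr, dead] = _death_prob(p_bc, p_ac, lr, conv)
    m[met, dead] = _death_prob(p_bc, p_ac, met, conv)
    m[dead, dead] = 1.0

    for state in ALIVE_STATES:
        stay = 1.0 - m[state].sum()
        if stay < 0:
            raise InfeasibleProbabilityError(
                f"{arm.arm_label}: outgoing probabilities from {state.name} "
                f"exceed 1 at cycle {cycle} (sum {m[state].sum():.6f})"
            )
        m[state, state] = stay
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy and transition flows of one simulated arm.

    ``occupancy`` has shape (horizon+1, 4): person-counts at each cycle
    boundary, row 0 = everyone disease-free.  ``flows`` has shape
    (horizon, 4, 4): persons moving from state i to state j during each
    cycle, so ``occupancy[t] = flows[t-1].sum(axis=0)``.
    """

    arm_label: str
    occupancy: np.ndarray
    flows: np.ndarray
    cohort_size: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self, cycle: int) -> float:
        """Persons in any alive state at the given cycle boundary."""
        return float(self.occupancy[cycle, : HealthState.DEATH].sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format occupancy table (cycle, state, count)."""
        records = [
            {"cycle": t, "state": s.name, "count": self.occupancy[t, s]}
            for t in range(self.horizon + 1)
            for s in HealthState
        ]
        return pd.DataFrame.from_records(records)

    def flows_frame(self) -> pd.DataFrame:
        """Long-format per-cycle flow table for the permitted transitions."""
        records = []
        for t in range(1, self.horizon + 1):
            for i in HealthState:
                for j in HealthState:
                    flow = self.flows[t - 1, i, j]
                    if flow != 0.0 or i == j:
                        records.append(
                            {"cycle": t, "from": i.name, "to": j.name, "count": flow}
                        )
        return pd.DataFrame.from_records(records)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "arm_label": self.arm_label,
                "cohort_size": self.cohort_size,
                "occupancy": self.occupancy.tolist(),
                "flows": self.flows.tolist(),
            }
        )


def run_cohort(
    arm: ArmParameters, mortality: MortalityTable, config: ModelConfig
) -> CohortTrace:
    """Propagate the cohort through the per-cycle transition matrices.

    Everyone starts disease-free; occupancy is taken at end of cycle.
    """
    occ = np.zeros((config.horizon + 1, _N))
    occ[0, HealthState.DISEASE_FREE] = config.cohort_size
    flows = np.zeros((config.horizon, _N, _N))
    for t in range(1, config.horizon + 1):
        m = build_transition_matrix(arm, mortality, config, t)
        flows[t - 1] = occ[t - 1][:, None] * m
        occ[t] = occ[t - 1] @ m
    return CohortTrace(
        arm_label=arm.arm_label,
        occupancy=occ,
        flows=flows,
        cohort_size=float(config.cohort_size),
    )
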