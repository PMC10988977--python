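"""Discounted benefits, costs, ICERs and dominance classification.

Benefits are per-patient discounted person-years: life-years (LY),
recurrence-free life-years (RFLY, time in the disease-free state), and
their quality-adjusted counterparts (QALY, QARFLY) obtained by weighting
state time with health-state utilities.  Costs are one-time per-patient
treatment and other direct costs, plus an allocation of the annual
equipment maintenance cost across the modelled cohort.  Pairwise
comparison yields incremental cost-effectiveness ratios (ICERs),
computed from unrounded incrementals, and a dominance label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conventions import END_OF_CYCLE, HealthState, ModelConventions
from .engine import CohortTrace
from .params import ArmParameters, ModelConfig, UtilitySet

__all__ = [
    "MEASURES",
    "OutcomeSet",
    "CEResult",
    "UndefinedICERError",
    "discount_factors",
    "discounted_state_time",
    "benefits",
    "per_patient_cost",
    "outcome_set",
    "icer",
    "classify_dominance",
    "compare",
    "ce_plane_frame",
]

#: Benefit measures, in reporting order.
MEASURES = ("ly", "rfly", "qaly", "qarfly")

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADE_OFF = "trade-off"


class UndefinedICERError(ZeroDivisionError):
    """Incremental benefit is zero; the ICER is undefined and the
    comparison must be decided on cost alone."""


def discount_factors(
    horizon: int, rate: float, conventions: ModelConventions
) -> np.ndarray:
    """Per-cycle discount weights for cycles 1..horizon."""
    t = np.arange(1, horizon + 1, dtype=float)
    exponent = t if conventions.discount_timing == END_OF_CYCLE else t - 1.0
    return (1.0 + rate) ** -exponent


def discounted_state_time(
    trace: CohortTrace, rate: float, conventions: ModelConventions
) -> np.ndarray:
    """Discounted person-years per patient in each state (length 4).

    Person-time in cycle t is the end-of-cycle occupancy, or the mean of
    the two cycle-boundary occupancies when the half-cycle correction is
    enabled; each cycle is weighted by its discount factor.
    """
    occ = trace.occupancy
    if conventions.half_cycle_correction:
        per_cycle = 0.5 * (occ[:-1] + occ[1:])
    else:
        per_cycle = occ[1:]
    d = discount_factors(trace.horizon, rate, conventions)
    return (per_cycle * d[:, None]).sum(axis=0) / trace.cohort_size


@dataclass(frozen=True)
class OutcomeSet:
    """Per-patient discounted benefits and cost for one arm."""

    arm_label: str
    ly: float
    rfly: float
    qaly: float
    qarfly: float
    cost: float

    def benefit(self, measure: str) -> float:
        if measure not in MEASURES:
            raise KeyError(f"unknown benefit measure {measure!r}")
        return getattr(self, measure)


def benefits(
    trace: CohortTrace, utilities: UtilitySet, config: ModelConfig
) -> dict[str, float]:
    """Discounted per-patient benefit measures for one traced arm."""
    time = discounted_state_time(
        trace, config.discount_rate_benefits, config.conventions
    )
    alive = time[: HealthState.DEATH]
    ly = float(alive.sum())
    rfly = float(time[HealthState.DISEASE_FREE])
    qaly = float(np.dot(time, utilities.as_vector()))
    qarfly = rfly * utilities.u_disease_free
    return {"ly": ly, "rfly": rfly, "qaly": qaly, "qarfly": qarfly}


def per_patient_cost(arm: ArmParameters, config: ModelConfig) -> float:
    """Per-patient cost: one-time treatment and other direct costs at
    model entry, plus the annual equipment maintenance cost allocated
    over the modelled cohort (skipped when maintenance is excluded).
    Entry costs are not discounted (cycle-0 outlay)."""
    cost = arm.cost_treatment + arm.cost_other_direct
    if config.include_maintenance:
        cost += arm.cost_annual_maintenance / config.cohort_size
    return cost


def outcome_set(
    trace: CohortTrace,
    arm: ArmParameters,
    utilities: UtilitySet,
    config: ModelConfig,
) -> OutcomeSet:
    """Bundle the benefit measures and per-patient cost for one arm."""
    b = benefits(trace, utilities, config)
    return OutcomeSet(arm_label=arm.arm_label, cost=per_patient_cost(arm, config), **b)


def icer(delta_cost: float, delta_benefit: float) -> float:
    """Incremental cost-effectiveness ratio from unrounded incrementals."""
    if delta_benefit == 0:
        raise UndefinedICERError(
            "incremental benefit is zero; decide on cost alone"
        )
    return delta_cost / delta_benefit


def classify_dominance(delta_cost: float, delta_benefit: float) -> str:
    """Dominance of the evaluated strategy versus its comparator."""
    if delta_cost > 0 and delta_benefit < 0:
        return DOMINATED
    if delta_cost < 0 and delta_benefit > 0:
        return DOMINANT
    return TRADE_OFF


@dataclass(frozen=True)
class CEResult:
    """Pairwise comparison (intervention minus comparator) on all measures."""

    intervention: OutcomeSet
    comparator: OutcomeSet
    delta_benefit: dict[str, float]
    delta_cost: float
    icers: dict[str, float | None]
    dominance: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        """Published-table layout: one row per measure plus a cost row."""
        rows = []
        for m in MEASURES:
            rows.append(
                {
                    "measure": m.upper(),
                    self.intervention.arm_label: self.intervention.benefit(m),
                    self.comparator.arm_label: self.comparator.benefit(m),
                    "incremental": self.delta_benefit[m],
                    "icer": self.icers[m],
                    "dominance": self.dominance[m],
                }
            )
        rows.append(
            {
                "measure": "COST",
                self.intervention.arm_label: self.intervention.cost,
                self.comparator.arm_label: self.comparator.cost,
                "incremental": self.delta_cost,
                "icer": None,
                "dominance": None,
            }
        )
        return pd.DataFrame.from_records(rows)


def compare(intervention: OutcomeSet, comparator: OutcomeSet) -> CEResult:
    """Incremental comparison of two arms on every benefit measure.

    ICERs are computed from the unrounded incrementals; where the
    incremental benefit is exactly zero the ICER is reported as None and
    the dominance label decides on cost alone.
    """
    delta_b = {m: intervention.benefit(m) - comparator.benefit(m) for m in MEASURES}
    delta_c = intervention.cost - comparator.cost
    icers: dict[str, float | None] = {}
    for m in MEASURES:
        try:
            icers[m] = icer(delta_c, delta_b[m])
        except UndefinedICERError:
            icers[m] = None
    dominance = {m: classify_dominance(delta_c, delta_b[m]) for m in MEASURES}
    return CEResult(
        intervention=intervention,
        comparator=comparator,
        delta_benefit=delta_b,
        delta_cost=delta_c,
        icers=icers,
        dominance=dominance,
    )


def ce_plane_frame(results: dict[str, CEResult]) -> pd.DataFrame:
    """Cost-effectiveness-plane coordinates (incremental benefit on x,
    incremental cost on y) for every analysis and measure."""
    rows = [
        {
            "analysis": name,
            "measure": m.upper(),
            "delta_benefit": res.delta_benefit[m],
            "delta_cost": res.delta_cost,
        }
        for name, res in results.items()
        for m in MEASURES
    ]
    return pd.DataFrame.from_records(rows)
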