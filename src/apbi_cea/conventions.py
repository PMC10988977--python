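"""Health states and the modelling conventions of the cohort engine.

The four-state structure (disease-free, local recurrence, metastasis,
death) is fixed.  A handful of modelling choices that published cohort
models frequently leave implicit — which states the disease-specific
death probabilities act from, how disease-specific and background
mortality combine, when within a cycle discounting starts, and whether a
half-cycle correction is applied — are made explicit and machine-
selectable here, so they can be enumerated and calibrated against
published results instead of being hard-coded.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field


class HealthState(enum.IntEnum):
    """Mutually exclusive health states; the integer value is the matrix index."""

    DISEASE_FREE = 0
    LOCAL_RECURRENCE = 1
    METASTASIS = 2
    DEATH = 3


#: Alive states, in matrix order.  DEATH is absorbing.
ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.DISEASE_FREE,
    HealthState.LOCAL_RECURRENCE,
    HealthState.METASTASIS,
)

ADDITIVE = "additive"
INDEPENDENT = "independent"
FIRST_CYCLE_UNDISCOUNTED = "first-cycle-undiscounted"
END_OF_CYCLE = "end-of-cycle"

_BC_SOURCE_OPTIONS: tuple[frozenset[HealthState], ...] = (
    frozenset({HealthState.LOCAL_RECURRENCE, HealthState.METASTASIS}),
    frozenset(ALIVE_STATES),
    frozenset({HealthState.METASTASIS}),
)


@dataclass(frozen=True)
class ModelConventions:
    """Resolvable modelling choices of the cohort model.

    Parameters
    ----------
    bc_death_source_states
        Alive states from which the annual breast-cancer death
        probability applies.  The default, ``{METASTASIS}``, is the
        configuration selected by calibration against the published
        per-arm expected values (see ``analyses.calibrate_conventions``).
    death_combination
        ``"additive"`` adds the disease-specific and all-cause
        probabilities; ``"independent"`` combines them as independent
        risks, ``1 - (1-p_bc)(1-p_ac)``.  At the magnitudes involved
        (< 0.03/year) the two differ by under 1e-4; the default is the
        calibration winner.
    discount_timing
        ``"first-cycle-undiscounted"`` weights cycle t by (1+r)^-(t-1);
        ``"end-of-cycle"`` by (1+r)^-t.
    half_cycle_correction
        When true, person-time per cycle is the mean of the occupancy at
        the two cycle boundaries rather than end-of-cycle occupancy.
    """

    bc_death_source_states: frozenset[HealthState] = frozenset(
        {HealthState.METASTASIS}
    )
    death_combination: str = INDEPENDENT
    discount_timing: str = FIRST_CYCLE_UNDISCOUNTED
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.death_combination not in (ADDITIVE, INDEPENDENT):
            raise ValueError(
                f"death_combination must be '{ADDITIVE}' or '{INDEPENDENT}', "
                f"got {self.death_combination!r}"
            )
        if self.discount_timing not in (FIRST_CYCLE_UNDISCOUNTED, END_OF_CYCLE):
            raise ValueError(
                f"discount_timing must be '{FIRST_CYCLE_UNDISCOUNTED}' or "
                f"'{END_OF_CYCLE}', got {self.discount_timing!r}"
            )
        bad = set(self.bc_death_source_states) - set(ALIVE_STATES)
        if bad:
            raise ValueError(f"bc_death_source_states must be alive states, got {bad}")
        object.__setattr__(
            self, "bc_death_source_states", frozenset(self.bc_death_source_states)
        )

    def describe(self) -> dict:
        """JSON-serializable description of this convention set."""
        return {
            "bc_death_source_states": sorted(
                s.name for s in self.bc_death_source_states
            ),
            "death_combination": self.death_combination,
            "discount_timing": self.discount_timing,
            "half_cycle_correction": self.half_cycle_correction,
        }


def convention_space() -> list[ModelConventions]:
    """Enumerate the full convention space searched by calibration.

    3 breast-cancer-death source sets x 2 death combinations x
    2 discount timings x 2 half-cycle settings = 24 configurations,
    in a fixed, deterministic order.
    """
    space = []
    for src, comb, timing, hcc in itertools.product(
        _BC_SOURCE_OPTIONS,
        (ADDITIVE, INDEPENDENT),
        (FIRST_CYCLE_UNDISCOUNTED, END_OF_CYCLE),
        (False, True),
    ):
        space.append(
            ModelConventions(
                bc_death_source_states=src,
                death_combination=comb,
                discount_timing=timing,
                half_cycle_correction=hcc,
            )
        )
    return space
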