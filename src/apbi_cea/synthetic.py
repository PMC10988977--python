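"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators:

* trial-style cumulative curves (IBTR incidence and overall survival)
  built from known annual hazards — exactly, or with per-year Bernoulli
  sampling noise on the at-risk set, the structure an empirical trial
  curve actually has — so the curve -> annual-probability stage can be
  tested by round trip against known truth;
* random valid model parameter bundles for engine property tests, with
  per-row outgoing-probability sums bounded away from 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import INCIDENCE, SURVIVAL, CumulativeCurve, cumulative_from_annual
from .params import (
    ArmParameters,
    ModelConfig,
    MortalityTable,
    ParameterBundle,
    UtilitySet,
)

__all__ = ["SyntheticTrialSpec", "generate_trial_curves", "generate_random_model_spec"]


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Known ground truth for a synthetic trial's published curves.

    ``hazards_ibtr`` and ``hazards_death`` are true annual event
    probabilities (length T).  With ``n_subjects`` set, curves carry
    binomial sampling noise from simulating that many subjects per
    outcome; ``rounding`` truncates the reported curves to the given
    number of decimals (published figures typically print 2-3).  A seed
    is mandatory whenever any stochastic element is enabled.
    """

    hazards_ibtr: tuple[float, ...]
    hazards_death: tuple[float, ...]
    n_subjects: int | None = None
    rounding: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("hazards_ibtr", "hazards_death"):
            vec = tuple(float(v) for v in getattr(self, name))
            if any(not 0.0 <= v <= 1.0 for v in vec):
                raise ValueError(f"{name} must lie in [0, 1]")
            object.__setattr__(self, name, vec)
        if len(self.hazards_ibtr) != len(self.hazards_death):
            raise ValueError("hazard vectors must have equal length")
        if self.n_subjects is not None and self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive when noise is enabled")
        if self.n_subjects is not None and self.seed is None:
            raise ValueError("seed is mandatory when sampling noise is enabled")


def _empirical_curve(hazards, n: int, rng: np.random.Generator, kind: str):
    """Simulate n subjects through per-year Bernoulli events on the
    at-risk set and return the empirical cumulative curve."""
    at_risk = n
    events_cum = 0
    values = [0.0 if kind == INCIDENCE else 1.0]
    for h in hazards:
        events = rng.binomial(at_risk, h)
        at_risk -= events
        events_cum += events
        if kind == INCIDENCE:
            values.append(events_cum / n)
        else:
            values.append(at_risk / n)
    return values


def generate_trial_curves(
    spec: SyntheticTrialSpec,
) -> tuple[CumulativeCurve, CumulativeCurve]:
    """Cumulative IBTR-incidence and overall-survival curves implied by
    the spec's true hazards (exact, or with sampling noise + rounding)."""
    if spec.n_subjects is None:
        incidence = cumulative_from_annual(spec.hazards_ibtr, INCIDENCE)
        survival = cumulative_from_annual(spec.hazards_death, SURVIVAL)
        inc_vals, surv_vals = list(incidence.values), list(survival.values)
    else:
        rng = np.random.default_rng(spec.seed)
        inc_vals = _empirical_curve(spec.hazards_ibtr, spec.n_subjects, rng, INCIDENCE)
        surv_vals = _empirical_curve(spec.hazards_death, spec.n_subjects, rng, SURVIVAL)
    if spec.rounding is not None:
        inc_vals = [round(v, spec.rounding) for v in inc_vals]
        surv_vals = [round(v, spec.rounding) for v in surv_vals]
        # re-impose monotonicity that rounding could nominally break
        inc_vals = list(np.maximum.accumulate(inc_vals))
        surv_vals = list(np.minimum.accumulate(surv_vals))
    return (
        CumulativeCurve(kind=INCIDENCE, values=tuple(inc_vals)),
        CumulativeCurve(kind=SURVIVAL, values=tuple(surv_vals)),
    )


def generate_random_model_spec(
    seed: int, probability_cap: float = 0.3, horizon: int = 10
) -> ParameterBundle:
    """Random valid parameter bundle, reproducible under ``seed``.

    Per-year recurrence and disease-free metastasis probabilities are
    drawn in [0, cap]; breast-cancer death and all-cause probabilities in
    [0, cap/2], so the worst-case outgoing sum from any state is at most
    3*cap (0.9 at the maximum cap of 0.3) under any convention.
    """
    if not 0.0 < probability_cap <= 0.3:
        raise ValueError(f"probability_cap must be in (0, 0.3], got {probability_cap}")
    rng = np.random.default_rng(seed)
    cap, half = probability_cap, probability_cap / 2.0

    def arm(label: str) -> ArmParameters:
        return ArmParameters(
            arm_label=label,
            p_local_recurrence=tuple(rng.uniform(0, cap, horizon)),
            p_bc_death=tuple(rng.uniform(0, half, horizon)),
            p_metastasis_from_disease_free=float(rng.uniform(0, cap)),
            p_metastasis_from_local_recurrence=float(rng.uniform(0, cap)),
            cost_treatment=float(rng.uniform(10, 1000)),
            cost_other_direct=float(rng.uniform(10, 1000)),
            cost_annual_maintenance=float(rng.uniform(0, 100_000)),
        )

    start_age = int(rng.integers(50, 71))
    bands = tuple(
        (start_age + 5 * i, start_age + 5 * i + 4, float(rng.uniform(0, half)))
        for i in range((horizon + 4) // 5)
    )
    u = np.sort(rng.uniform(0.3, 1.0, 3))
    utilities = UtilitySet(
        u_disease_free=float(u[2]),
        u_local_recurrence=float(u[1]),
        u_metastasis=float(u[0]),
    )
    config = ModelConfig(
        cohort_size=float(rng.integers(10, 1000)),
        start_age=start_age,
        horizon=horizon,
        discount_rate_benefits=float(rng.uniform(0, 0.1)),
        discount_rate_costs=float(rng.uniform(0, 0.1)),
    )
    base = arm("ARM-A")
    return ParameterBundle(
        iort=base,
        imrt=arm("ARM-B"),
        iort_lower_recurrence=base,
        iort_lower_metastasis=base,
        mortality=MortalityTable(bands=bands),
        utilities=utilities,
        config=config,
    )
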