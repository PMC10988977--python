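"""Independent cross-check oracles for the deterministic cohort engine."""

import numpy as np

from apbi_cea.conventions import ADDITIVE, HealthState

DF, LR, MET, DEAD = HealthState


def microsimulate(arm, mortality, config, n_patients, rng):
    """Stochastic microsimulation of ``n_patients`` independent patients.

    Implements the model's transition rules directly with per-cycle
    multinomial draws over each state's competing outcomes (equivalent
    to simulating every patient's Bernoulli transitions independently),
    without using the engine's matrices.  Returns occupancy fractions
    with shape (horizon+1, 4).
    """
    conv = config.conventions
    occ = np.zeros((config.horizon + 1, 4))
    current = np.zeros(4, dtype=np.int64)
    current[DF] = n_patients
    occ[0] = current / n_patients
    for t in range(1, config.horizon + 1):
        age = config.start_age + t - 1
        p_ac = mortality.annual_probability(age)
        p_bc = arm.p_bc_death[t - 1]

        def p_death(state):
            bc = p_bc if state in conv.bc_death_source_states else 0.0
            if conv.death_combination == ADDITIVE:
                return bc + p_ac
            return 1.0 - (1.0 - bc) * (1.0 - p_ac)

        nxt = np.zeros(4, dtype=np.int64)
        # disease-free: stay / local recurrence / metastasis / death
        p = [arm.p_local_recurrence[t - 1], arm.p_metastasis_from_disease_free,
             p_death(DF)]
        draws = rng.multinomial(current[DF], [1.0 - sum(p)] + p)
        nxt[[DF, LR, MET, DEAD]] += draws
        # local recurrence: stay / metastasis / death
        p = [arm.p_metastasis_from_local_recurrence, p_death(LR)]
        draws = rng.multinomial(current[LR], [1.0 - sum(p)] + p)
        nxt[[LR, MET, DEAD]] += draws
        # metastasis: stay / death
        p = [p_death(MET)]
        draws = rng.multinomial(current[MET], [1.0 - sum(p)] + p)
        nxt[[MET, DEAD]] += draws
        nxt[DEAD] += current[DEAD]
        current = nxt
        occ[t] = current / n_patients
    return occ
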