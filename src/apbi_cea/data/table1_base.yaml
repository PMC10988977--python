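# Base-case model parameters, transcribed from the published parameter
# table.  Probabilities are annual; costs are 2021 USD per patient
# (maintenance is per equipment-year).  This file is the single source
# of truth for the bundled parameter sets.
arms:
  IORT:
    p_local_recurrence: [0.000, 0.001, 0.018, 0.009, 0.005, 0.016, 0.001, 0.012, 0.010, 0.006]
    p_bc_death: [0.003, 0.002, 0.006, 0.008, 0.017, 0.018, 0.006, 0.011, 0.008, 0.018]
    p_metastasis_from_disease_free: 0.006
    p_metastasis_from_local_recurrence: 0.03
    cost_treatment: 418
    cost_other_direct: 359
    cost_annual_maintenance: 55344
  IMRT:
    p_local_recurrence: [0.002, 0.004, 0.004, 0.011, 0.000, 0.000, 0.004, 0.008, 0.000, 0.000]
    p_bc_death: [0.004, 0.004, 0.006, 0.006, 0.006, 0.003, 0.012, 0.010, 0.017, 0.005]
    p_metastasis_from_disease_free: 0.0029
    p_metastasis_from_local_recurrence: 0.03
    cost_treatment: 29
    cost_other_direct: 294
    cost_annual_maintenance: 0
mortality:
  - {age_low: 50, age_high: 54, p: 0.002}
  - {age_low: 55, age_high: 59, p: 0.004}
  - {age_low: 60, age_high: 64, p: 0.006}
  - {age_low: 65, age_high: 69, p: 0.009}
utilities:
  disease_free: 0.920
  local_recurrence: 0.779
  metastasis: 0.685
config:
  cohort_size: 100
  start_age: 60
  horizon: 10
  cycle_length: 1
  discount_rate_benefits: 0.03
  discount_rate_costs: 0.03
  include_maintenance: true
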