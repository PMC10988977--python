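# Methods

## Model structure

The engine is a deterministic Markov cohort model with four mutually
exclusive health states — disease-free (DF), local recurrence (LR),
metastasis (M), death (D) — in annual cycles.  The whole cohort starts
disease-free.  Permitted transitions are one-way: DF→{LR, M, D},
LR→{M, D}, M→D; death is absorbing.  There is no salvage back to the
disease-free state, no tunnel states, and no patient-level
heterogeneity.  Per cycle a 4×4 row-stochastic matrix is built and the
occupancy vector propagated; per-entry flow products are retained so
that incidence-of-entry quantities (e.g. cumulative local recurrence)
can be measured as flows rather than state occupancy.

Competing transition probabilities within a row combine additively,
with the stay probability as the remainder (no hazard-based rescaling):
annual probabilities here are small (worst row sum ≈ 0.06 for the
bundled sets), so the additive approximation is well inside rounding
error, and the engine raises a named infeasibility error for any
state/cycle whose outgoing sum exceeds 1.

## Parameters

All bundled inputs live in `src/apbi_cea/data/table1_base.yaml` and
`table1_sensitivity.yaml` (single source of truth, loaded by
`builtin_table1()`):

* `p_local_recurrence`, `p_bc_death` — annual probabilities for years
  1–10 since surgery, per arm.  They are clocked by model cycle (time
  since surgery), not by time-in-state, because they derive from
  trial-level curves clocked from randomization.
* `p_metastasis_from_disease_free` — fixed annual probability (IORT
  0.006, IMRT 0.0029; sensitivity variant 0.004), used because no
  metastasis curve is available.
* `p_metastasis_from_local_recurrence` — 0.03/year, time-homogeneous
  (memoryless), both arms.
* Background mortality — annual all-cause death probability in closed
  5-year age bands (50–54: 0.002 … 65–69: 0.009).  The cohort enters at
  exactly age 60, so cycle t uses age 60+t−1 and the band switch falls
  at cycle 6 (age 65).  The 50–59 bands are unreachable for the default
  cohort but retained for generality.
* Utilities — DF 0.920, LR 0.779, M 0.685 (dimensionless weights).  The
  published utility set labels its third state "other recurrences"; the
  package applies it to the metastasis state, the only remaining
  non-death state.
* Costs — 2021 USD per patient: treatment (IORT 418 / IMRT 29), other
  direct (359 / 294), and IORT annual equipment maintenance 55,344 per
  equipment-year.  The currency-conversion note (1 USD = 786 CLP) is
  metadata; no conversion is implemented.
* Run configuration — cohort 100, start age 60, horizon 10 one-year
  cycles, 3%/yr discount rates for benefits and costs.

Config files mirror these field names (YAML/JSON mapping; unknown keys
rejected with the offending field named); curves use two-column CSV
(year, value).

## Curve-to-probability derivation

Annual conditional probabilities are estimated from cumulative curves
on the at-risk set: for a cumulative-incidence curve
p[t] = (C[t]−C[t−1])/(1−C[t−1]); for a survival curve
p[t] = 1 − S[t]/S[t−1].  This is a cause-specific read of the curve
without competing-risk correction.  `cumulative_from_annual` is the
exact algebraic inverse (round-trip tested to 1e−12).  The bundled
analysis starts from the already-derived annual probabilities, so this
stage is exercised through the synthetic-trial generator.

## Conventions and calibration

Four choices the published model description leaves open are explicit
settings (`ModelConventions`):

1. which alive states the disease-specific (breast-cancer) death
   probabilities act from — {LR, M}, all alive states, or {M};
2. additive vs independent combination of disease-specific and
   background mortality (difference < 1e−4 at these magnitudes);
3. discount timing — first-cycle-undiscounted, weight (1+r)^−(t−1), vs
   end-of-cycle, (1+r)^−t;
4. half-cycle correction on person-time (mean of cycle-boundary
   occupancies) — on/off.

`calibrate_conventions` enumerates all 3×2×2×2 = 24 configurations and
scores each by summed relative error against the published per-arm
expected benefits, costs, and the two validation metrics.  The search
is deterministic and its full score table is an output (`apbi-cea
calibrate`), so the choice is documented, not a hidden fudge.  The
argmin — disease-specific death from the metastasis state only,
independent combination, first-cycle-undiscounted, no half-cycle
correction — is the package default.  The ranking is decisive on the
first and third axes: applying breast-cancer death from the
disease-free state drags 10-year survival to ≈ 84% versus the ≈ 92.5%
the published model reports, and end-of-cycle discounting shaves ≈ 0.25
discounted years off every arm; the second axis is numerically almost
indifferent and the argmin simply falls on the independent side.

## Outcomes and costs

Discounted per-patient state time is Σ_t occupancy[t]·d(t)/cohort; LY
sums the three alive states, RFLY is DF time, QALY is utility-weighted
state time, and QARFLY = RFLY × u_DF exactly.  Costs are incurred once
at model entry (treatment + other direct), so the cost discount rate is
implemented but has no effect on the bundled runs; the annual
maintenance cost is allocated as maintenance/cohort_size (553.44 per
patient at the defaults), which reconciles the published per-patient
totals, and is dropped entirely in the no-maintenance scenario (and via
`include_maintenance=false`).  ICERs are computed from unrounded
incrementals; reporting helpers round benefits to 2 decimals and
currency to whole dollars.  When an incremental benefit is exactly
zero the ICER is reported as undefined and the comparison decided on
cost alone.

Validation metrics are computed for the IORT arm by default (its
published comparators are IORT-based studies, and the arm is
configurable): cumulative 10-year local recurrence is the sum of DF→LR
entry flows per cohort member — incidence of entry, comparable to trial
IBTR rates — and 10-year overall survival is the alive fraction at the
final cycle boundary.

## Synthetic data

`SyntheticTrialSpec`/`generate_trial_curves` emulate the *published
curve* stage of a trial: known annual hazards produce exact cumulative
curves, optionally with per-year Bernoulli sampling on the at-risk set
(the noise structure an empirical curve actually has) and
published-figure rounding (2–3 decimals).  They do not emulate
censoring, staggered accrual, competing-risk estimators, or
confidence intervals — so passing round-trip tests shows the derivation
is correct for cause-specific curves, not that it is robust to those
real-data features.  `generate_random_model_spec` draws valid random
parameter bundles (per-row outgoing sums ≤ 3×cap ≤ 0.9 by construction,
ordered utilities, positive costs) for engine property tests, both
reproducible by seed.

## Numerical choices

Row-stochasticity holds to 1e−12 and cohort conservation to 1e−9 (pure
linear algebra, float64).  The deterministic trace is cross-checked
against an independent stochastic microsimulation (multinomial draws
per state and cycle, 1e5 patients, 3 binomial standard errors) in the
test suite.  Degenerate inputs: all-zero probability sets are valid and
propagate unchanged; a cumulative curve that saturates (C=1 or S=0) and
then moves again is rejected; calibration ties resolve to the first
configuration in the fixed enumeration order.

## Known limitations

* Inputs are the printed, rounded parameter values.  Ratio outcomes
  with small denominators amplify that rounding: the sensitivity-
  analysis ICERs shift by ~5–10% for a 0.0005 change in the fixed
  metastasis probability (the printed value carries only one
  significant figure), while base-case and scenario ICERs, whose
  denominators are pinned by the year-resolved vectors, are stable to
  ~2%.
* The 10-year horizon is not extrapolated; nothing is claimed beyond
  cycle 10.
* No probabilistic sensitivity analysis, willingness-to-pay decision
  rule, net monetary benefit, or budget impact — the pipeline covers
  the four deterministic experiments only.
* Adverse-event/complication costs, follow-up costs, and the initial
  equipment investment are excluded by design (disinvestment
  perspective: only use-associated costs of already-owned equipment).
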