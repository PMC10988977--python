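# apbi-cea

A Markov cohort cost-effectiveness analysis of two accelerated partial
breast irradiation (APBI) techniques for early-stage breast cancer after
breast-conserving surgery: electron-based intraoperative radiotherapy
(IORT) versus intensity-modulated radiotherapy (IMRT).  The package is a
disinvestment-analysis pipeline for health-technology-assessment
analysts: it reproduces the published base case, both one-way
sensitivity analyses, the no-maintenance-cost scenario, and the model
validation metrics from the published parameter table, as tested,
configurable code.

## The model

A deterministic cohort of 100 women aged 60 moves through four mutually
exclusive health states in annual cycles over a 10-year horizon:

    disease-free → local recurrence → metastasis → death

with direct transitions disease-free → metastasis/death and local
recurrence → death also permitted; death is absorbing and progression is
one-way.  Local recurrence and breast-cancer death probabilities are
time-dependent (annual values for years 1–10 derived from trial
cumulative-incidence and overall-survival curves, a derivation the
`curves` module implements and round-trip tests); metastasis
probabilities are fixed annual rates; background mortality comes from
age-banded national life tables.  Benefits per arm are discounted (3%/yr)
per-patient life-years (LY), recurrence-free life-years (RFLY), and
their quality-adjusted counterparts (QALY, QARFLY) using health-state
utilities; costs are per-patient treatment and other direct costs plus
the annual IORT equipment maintenance cost allocated across the cohort.
Strategies are compared by incremental cost-effectiveness ratios,

    ICER = ΔC / ΔE  (IORT − IMRT, unrounded incrementals),

with a dominance label per benefit measure.

Four modelling conventions the published description leaves open (which
states disease-specific mortality acts from, additive vs independent
death combination, discount timing, half-cycle correction) are explicit,
enumerable settings; `calibrate_conventions` searches all 24
configurations against the published expected values and the package
defaults to the winner.

## Worked example

```sh
$ apbi-cea run --out out/
validation (IORT): 10-y LR 7.09%, 10-y OS 92.44%
base case LY      IORT 8.47 IMRT 8.48 incr -0.0054 ICER -187,207 (dominated)
base case RFLY    IORT 7.92 IMRT 8.19 incr -0.2660 ICER -3,788 (dominated)
base case QALY    IORT 7.69 IMRT 7.75 incr -0.0542 ICER -18,572 (dominated)
base case QARFLY  IORT 7.29 IMRT 7.54 incr -0.2447 ICER -4,117 (dominated)
base case costs   IORT 1,330 IMRT 323 incr +1,007
```

The model predicts a 7.09% 10-year cumulative local-recurrence rate and
92.44% 10-year overall survival for the IORT arm (its validation
surface).  IORT buys slightly fewer benefits on every measure at ~$1,007
more per patient — mostly the $553/patient maintenance allocation — so
it is dominated: negative ICERs here mean "pay more, get less".  The run
also writes `table2.csv` (all four analyses), `validation.json`,
`ce_plane.csv` (incremental benefit/cost coordinates per analysis and
measure) and a manifest.  `apbi-cea calibrate` writes the 24-row
convention score table; `apbi-cea synth-curves --seed N` generates
synthetic trial curves from known hazards for testing the
curve-to-probability derivation.

The same API is available in Python:

```python
from apbi_cea import builtin_table1, run_full_suite

suite = run_full_suite(builtin_table1())
print(suite.base_case.icers["rfly"])   # -3787.6
print(suite.validation["IORT"])
```

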