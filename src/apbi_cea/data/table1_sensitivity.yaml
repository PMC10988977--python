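# One-way sensitivity parameter sets for the IORT arm: local-recurrence
# probabilities at the lower confidence limit of the trial recurrence
# curve, and the metastasis probability at the lower limit of the
# published 10-year rate.  Each variant replaces only the named block.
variants:
  lower_recurrence:
    p_local_recurrence: [0.000, 0.000, 0.010, 0.008, 0.006, 0.011, 0.002, 0.010, 0.008, 0.005]
  lower_metastasis:
    p_metastasis_from_disease_free: 0.004
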