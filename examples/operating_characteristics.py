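"""Simulate operating characteristics of the default 5-dose design.

Runs 1000 trials of 24 patients (cohorts of 2, starting at dose 1) under
a true dose-toxicity curve equal to the skeleton values, so dose 3 is the
true MTD with DLT probability exactly at the 0.25 target.
"""

import numpy as np

import crmkit as ck

design = ck.resolve_design(0.25, 5, cohort_size=2, max_n=24, start_dose=1)
scenario = ck.Scenario(true_probs=tuple(np.round(design.skeleton, 2)))
config = ck.SimConfig(design=design, scenario=scenario, nsim=1000, seed=1)

oc = ck.simulate_ocs(config)
print(ck.render_oc(oc))

# "% selected as MTD" row: how often each dose is declared the MTD after
# 24 patients -- the dose-3 entry is the percentage of correct selection.
# "Mean # patients" shows where patients are treated on average; a safe,
# accurate design concentrates them at and just below the true MTD.
# Re-running with the same seed reproduces the table exactly.
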