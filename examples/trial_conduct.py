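"""Conduct mode: sequential dose recommendations as DLT data accumulate.

Replays the early course of a trial run in cohorts of two: no DLTs in the
first two cohorts, then one DLT among four patients at dose 3.
"""

import crmkit as ck

design = ck.resolve_design(0.25, 5, cohort_size=2, max_n=24)

# cohort 1: 0/2 DLTs at dose 1
state = ck.TrialState(y=(0, 0, 0, 0, 0), n=(2, 0, 0, 0, 0), current_dose=1)
rec = ck.next_action(state, design)
print(ck.render_recommendation(rec))
print()

# cohort 2: 0/2 DLTs at dose 2
state = state.with_cohort(2, 2, 0)
rec = ck.next_action(state, design)
print(ck.render_recommendation(rec))
print()

# cohorts 3-4: 1/4 DLTs at dose 3
state = state.with_cohort(3, 4, 1)
rec = ck.next_action(state, design)
print(ck.render_recommendation(rec))

# After 0/2 at dose 1 the model's best guess for the MTD is dose 3
# (estimated DLT rate 0.21), but the no-skip rule caps escalation at dose
# 2.  After 0/2 more at dose 2 the model points to dose 4 (0.27) and the
# cap yields dose 3.  One DLT in four patients at dose 3 keeps the
# recommendation at dose 3 -- the estimate there is again nearest 0.25.
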