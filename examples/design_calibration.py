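"""Calibrate a default CRM design: skeleton and least-informative prior.

Builds the working-model skeleton for a 5-level trial targeting a 25% DLT
rate, with the prior MTD at the median dose, then calibrates the prior SD
so the prior is maximally vague about which dose is the MTD.
"""

import numpy as np

import crmkit as ck

req = ck.SkeletonRequest(delta=0.05, theta=0.25, nu=3, K=5)
skeleton = ck.generate_skeleton(req)
sigma = ck.least_informative_sigma(skeleton, req.theta)
q = ck.prior_mtd_probs(skeleton, req.theta, sigma)

print("Skeleton (2 d.p.):", np.round(skeleton, 2))
print(f"Least-informative prior SD: {sigma:.2f}")
print("Prior P(dose k is the MTD):", np.round(q, 3))

# The skeleton values are the model's initial DLT-probability guesses,
# anchored at the target (0.25) at dose 3 and spaced so neighbouring doses
# stay distinguishable within +/-0.05 of the target.  The prior-MTD
# probabilities are close to uniform (1/5 each): before any data, the
# design holds no strong view of where the MTD lies.
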