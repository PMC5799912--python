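# crmkit

Bayesian continual reassessment method (CRM) for phase I dose-finding
trials: design calibration, sequential trial conduct, and Monte-Carlo
simulation of operating characteristics.

Phase I oncology trials search a ladder of doses `d_1 < ... < d_K` for the
maximum tolerated dose (MTD) — the dose whose probability of a
dose-limiting toxicity (DLT) is closest to a protocol target `θ`
(typically 0.20–0.33). The CRM is the model-based alternative to 3+3-style
escalation: it fits a one-parameter working model to all accumulated DLT
data and treats each new cohort at the dose currently estimated to be the
MTD. `crmkit` is for trial statisticians who need protocol-ready operating
characteristics at the design stage and auditable dose recommendations
during conduct.

## Model

The *empiric* (power) working model

&nbsp;&nbsp;&nbsp;&nbsp;R(d_k) = Pr(DLT at d_k) ≈ α_k^exp(a),

where `α_1 < ... < α_K` is the skeleton of initial DLT-probability guesses
and `a` has a mean-zero normal prior N(0, σ_a²). After each cohort the
posterior mean `â` is computed by numerical quadrature, DLT probabilities
are estimated by plug-in `p̂_k = α_k^exp(â)`, and the next cohort is
assigned to `argmin_k |p̂_k − θ|`, with two protections:

* **no-skip escalation** — never more than one level above the most recent
  dose;
* **safety stop** — the trial halts if the lower limit of the central 90%
  posterior probability interval for R(d_1) exceeds `θ`.

Two design quantities are calibrated automatically:

* **skeleton** via the indifference-interval recursion: `α_ν = θ` at the
  prior-MTD dose ν (default: the median dose), and neighbours are spaced
  so adjacent doses remain distinguishable within `θ ± δ` (default
  δ = 0.05);
* **least-informative prior SD** `σ_a`: chosen so the prior probability
  that each dose is the MTD is as close to uniform (1/K) as possible.

## Worked example

```python
import numpy as np
import crmkit as ck

design = ck.resolve_design(0.25, 5, cohort_size=2, max_n=24)
print(np.round(design.skeleton, 2), design.sigma_a)
# [0.08 0.16 0.25 0.35 0.46] 0.53

state = ck.TrialState(y=(0, 0, 0, 0, 0), n=(2, 0, 0, 0, 0), current_dose=1)
rec = ck.next_action(state, design)
print(np.round(rec.posterior.p_hat, 2), rec.dose)
# [0.06 0.12 0.21 0.31 0.42] 2
```

After two patients with no DLT at dose 1, the updated estimates put dose 3
nearest the 0.25 target (estimated rate 0.21), but the no-skip rule caps
the recommendation at dose 2. The same engine drives the simulator:

```python
scenario = ck.Scenario(true_probs=tuple(np.round(design.skeleton, 2)))
oc = ck.simulate_ocs(ck.SimConfig(design=design, scenario=scenario, nsim=1000, seed=1))
print(ck.render_oc(oc))
```

```
Dose level            1     2     3     4     5
Skeleton              0.08  0.16  0.25  0.35  0.46
True DLT probability  0.08  0.16  0.25  0.35  0.46
% selected as MTD     2.2   22.8  50.7  21.8  2.5
Mean # DLTs           0.2   1.1   2.4   1.5   0.4
Mean # patients       2.7   6.9   9.4   4.2   0.8
% trials stopped for safety: 0.0
nsim: 1000   seed: 1
```

The dose-3 column is the percentage of correct selection (the true MTD
here is dose 3 at exactly 0.25); the patient row shows where the design
treats patients on average. Identical seed, identical table.

The same operations are available from a shell:

```bash
crmkit skeleton --target 0.25 --n-doses 5
crmkit next-dose --target 0.25 --n-doses 5 --dlts 0,0,0,0,0 \
    --patients 2,0,0,0,0 --current-dose 1
crmkit simulate --target 0.25 --n-doses 5 --true-probs 0.08,0.16,0.25,0.35,0.46 \
    --nsim 1000 --seed 1 --format markdown
```

Longer narrated versions live in `examples/`.

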