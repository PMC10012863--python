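# rtplanqa

A Bayesian-network assistant for the initial review of radiotherapy
treatment plans.

Before a plan is delivered, physicists check dozens of technical and
prescription parameters — beam energy, gantry and collimator angles, the
fractionation scheme, monitor-unit complexity surrogates — against what is
clinically plausible for the patient. `rtplanqa` automates the statistical
half of that check: it learns a discrete Bayesian network over 24 plan
variables from historical treatment plans, and for every new plan scores
each variable by its conditional probability given the rest of the plan.
Improbable values are flagged as potential errors with pass / alert /
warning tiers. The package also ships everything needed to study the
approach across institutions: a synthetic multi-clinic cohort generator,
a simulated-error injector, and a ROC/AUC evaluation harness covering
single-site, cross-site, two-on-one and pooled training set-ups.

## The model

The 24 plan variables (5 diagnostic, 5 patient-setup, 11 treatment-planning,
3 dose-prescription) form a directed acyclic graph with 41 edges; the joint
distribution factorizes as

```
P(x_1, ..., x_24) = prod_i P(x_i | pa(x_i))
```

Parameters are learned by expectation-maximization (records may have
missing values) with a Laplace pseudocount of `1/q_i` per CPT cell, where
`q_i` is the number of parent-state combinations of node `i` — so with
complete data the estimate is the closed form
`(N_ijk + 1/q_i) / (N_ij + r_i/q_i)` and no probability is ever exactly
zero. EM stops when the relative change of the penalized log-likelihood
falls below `1e-4`.

A plan variable `X = x` is scored by the exact posterior
`P(X = x | evidence)`, computed by variable elimination, under one of two
evidence strategies: *diagnostic-only* (instantiate the TNM stages,
anatomic tumor location and treatment intent) or *all-but-target*
(instantiate every other observed variable). Scores below the anomaly
threshold (default 0.05) raise an alert; below the warning threshold
(default 0.01), a warning. Detection quality is measured by sweeping the
anomaly threshold over all scores and computing the area under the ROC
curve, per variable and pooled.

## Worked example

`examples/01_score_a_plan.py` builds a coherent curative lung plan
(6000 cGy prescribed at 200–250 cGy per fraction) and then corrupts the
fraction count to a 1–5 fraction course:

```
variable              state              P(state|rest)  tier
number_of_fractions   1-5                       0.0002  warning
dose_per_fraction     [200,250)                 0.0052  warning
ptv_dose              [6000,6500)               0.0649  pass
collimator_angle      [10,20)                   0.2435  pass
...
radiation_type        photon                    0.9992  pass

2 of 19 variables flagged
```

The corrupted fraction count is the most improbable value in the plan
(P = 0.0002): 6000 cGy cannot be delivered in 1–5 fractions of ~200 cGy.
`dose_per_fraction` is dragged below threshold with it because the two
variables are coupled through the prescription arithmetic, while every
consistent parameter passes.

`examples/02_learn_inject_evaluate.py` runs the in-clinic loop (sample
2000 plans, 80/20 split, EM training, 5% error injection, ROC) and
`examples/03_multi_site_experiments.py` contrasts single-site, cross-site
and pooled training across three synthetic clinics with divergent practice
profiles.

There is also a thin CLI over the same library calls:

```sh
rtplanqa simulate --seed 3 --n-per-clinic 500 --out plans.csv
rtplanqa train    --plans plans.csv --out net.xmlbif
rtplanqa detect   --network net.xmlbif --plans plans.csv --out scores.csv
```

Every command writes a JSON run manifest (config, seeds, file digests)
next to its outputs.

## Layout

- `src/rtplanqa/schema.py` — plan data model, binning, CSV/YAML IO, splits
- `src/rtplanqa/network.py` — the Bayesian network: exact inference, EM,
  XMLBIF serialization
- `src/rtplanqa/defaults.py`, `ground_truth.py` — the 24-variable
  vocabulary, the 41-edge structure and the authored synthetic ground truth
- `src/rtplanqa/synthetic.py` — multi-clinic cohort generator
- `src/rtplanqa/inject.py` — simulated-error injector (setup / planning /
  prescription categories)
- `src/rtplanqa/detect.py` — scoring and tiering
- `src/rtplanqa/evaluate.py` — ROC/AUC and the four experiment set-ups
- `docs/methods.md` — model, assumptions, parameter choices, limitations
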