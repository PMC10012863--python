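# Methods

## The model and its intended use

`rtplanqa` models a radiotherapy treatment plan as a joint distribution
over 24 discrete variables: five diagnostic variables (T, N and M stage,
anatomic tumor location, treatment intent), five patient-setup variables
(bolus, orientation, table angle, tolerance table, image guidance), eleven
treatment-planning variables (technique, radiation type, beam energy,
number of beams, SSD, collimator and gantry angles, wedge, MU/cGy,
MU/degree, dose rate) and three dose-prescription variables (PTV dose,
number of fractions, dose per fraction). The distribution is a Bayesian
network: a DAG with one conditional probability table (CPT) per node.

The intended use is anomaly detection at initial plan review. Given a new
plan, some variables are instantiated as evidence and each remaining
variable of interest is scored by the exact posterior probability of its
observed state. A value that is improbable given the rest of the plan is
either a rare-but-valid clinical choice or an error; the tool surfaces it
and a human decides. Diagnostic variables are always treated as evidence,
never scored — they are confirmed upstream of planning.

## The shipped structure

The default DAG has 24 nodes and 41 edges, authored from clinical
dependency reasoning: diagnosis drives intent, intent and site drive
technique and the prescription, technique drives beam geometry, delivery
parameters and the complexity surrogates, and the prescription triplet is
internally coupled (PTV dose -> fractions -> dose per fraction). The node
and edge counts are asserted at construction; the edge list lives in
`defaults.DEFAULT_EDGES` and can be replaced by any user DAG via the
edge-list text format or XMLBIF. Structure learning is deliberately out of
scope — the graph encodes expert knowledge, not data.

## Discretization

Continuous quantities are binned before modelling, coarsely enough to be
learnable from a few thousand plans and finely enough that the canonical
simulated error magnitudes always change the state:

| quantity | bins | unit |
|---|---|---|
| table / gantry / collimator angle | 36 x 10 degrees over [0, 360) | degrees |
| dose per fraction | 50 cGy wide to 500, then one open top bin | cGy |
| PTV dose | 500 cGy wide to 8000, then one open top bin | cGy |
| number of fractions | 1-5, 6-10, ..., 36-40, >40 | count |
| MU/cGy, MU/degree | five fixed quantile-style bins | ratio |
| SSD | 10 cm wide over [60, 110) | cm |

A 10 degree table-angle offset moves exactly one bin; a 20-30 degree
gantry offset moves two or three. Binning is total, deterministic,
lower-inclusive and half-open; out-of-domain raw values map to a reserved
out-of-range label rather than silently to missing. All vocabularies and
cut points are overridable through the YAML schema file.

## Parameter learning

CPTs are estimated by expectation-maximization with a Dirichlet
(Laplace) prior whose pseudocount per CPT cell is `1/q_i`, the inverse of
the node's number of parent-state combinations. This keeps each node's
total prior weight bounded (one pseudo-observation per state across all
rows) and guarantees strictly positive probabilities, so no observed
evidence combination is ever "impossible" at scoring time.

* With complete data the M-step is closed-form:
  `theta = (N_ijk + 1/q_i) / (N_ij + r_i/q_i)`; EM terminates after one
  iteration.
* With missing values, records are grouped by (missing-variable set,
  observed values on the affected families); each group's exact posterior
  over its missing variables is computed by factor products, giving exact
  expected counts. The update maximizes the penalized expected
  log-likelihood, so the penalized observed-data log-likelihood is
  non-decreasing across iterations (checked by a property test).
* Convergence: relative change of the penalized log-likelihood below
  `1e-4` (the metric is the package's choice; the threshold is the
  conventional one), capped at 200 iterations. Initialization is the
  deterministic available-case estimate, so learning is reproducible
  without any seed.

## Inference

Marginals are exact: barren-node pruning (only ancestors of the query and
evidence are kept) followed by sum-product variable elimination with a
greedy smallest-factor ordering. The 24-node network's treewidth is small,
so no approximate inference is needed or offered. Two exact fast paths
matter for throughput:

* under the all-evidence strategy, a target whose Markov blanket is fully
  observed is scored from its own CPT row times its children's rows;
* under the diagnostic-only strategy, posteriors are cached per distinct
  evidence assignment, collapsing a cohort onto a few hundred eliminations.

Both paths are tested for equality against full elimination and against a
brute-force enumeration of the joint.

## Synthetic cohorts

No institutional plan data are distributed, so the multi-clinic studies
run on synthetic cohorts. The generator emulates three statistical
features of real multi-institutional data:

1. **Clinic-specific practice.** All clinics share the structure; each
   clinic's CPT rows are a Dirichlet resample of a common hand-authored
   ground truth with concentration `15 / divergence`. Divergence 0 means
   identical clinics; divergence 1.0 puts the mean per-row total-variation
   distance between two clinics near 0.2.
2. **Structural non-applicability.** One default clinic carries no wedge
   or tolerance-table fields at all (sampled, then dropped), emulating a
   planning system that does not record them.
3. **Record-level missingness.** Missing-at-random per variable, default
   rates 2-8% by variable.

The authored ground truth encodes broad practice patterns (palliative
intent favours short schedules; VMAT means one or two photon arcs with
daily CBCT; breast 3D-CRT uses opposed tangents; the prescription triplet
is arithmetically coherent through bin representatives). It is synthetic:
authored for dependency structure, not fitted to any institution. What
passing tests show is therefore that the method behaves as designed under
these dependency structures — not that any particular AUC transfers to
real clinical data, whose heterogeneity (temporal drift, free-text fields,
correlated missingness, within-site practice variation beyond what
diagnosis explains) the generator does not model.

## Error simulation

Five percent of test plans (exactly `round(0.05 n)`, configurable) receive
one error event each, drawn from three equally weighted categories:

* **setup** — table angle shifted exactly one 10 degree bin (random
  direction, wrap at 360), bolus toggled, orientation or tolerance table
  swapped to a different state;
* **planning** — gantry or collimator shifted by a uniform 20-30 degree
  offset and re-binned, MU/cGy or MU/degree forced to an extreme bin,
  beam energy / radiation type / number of beams / SSD / wedge swapped
  uniformly;
* **prescription** — three schemes: (1) dose per fraction and fraction
  count change jointly with the total dose bin preserved, (2) PTV dose and
  fraction count change with dose per fraction held, (3) PTV dose and dose
  per fraction change with fraction count held. A prescription event can
  legitimately change two variables; one injection record is written per
  variable actually changed.

Every injected value is a legal vocabulary state. Incompatible draws (a
variable with no alternative state, or missing on that plan) are redrawn
and logged.

## Evaluation

Each scored (plan, variable) pair is an instance, labelled positive when
it was injected. Ranking is by the marginal probability — lower is more
anomalous — and the ROC sweeps the anomaly threshold over all distinct
scores; AUC uses the trapezoidal rule, equivalent to the Mann-Whitney
statistic with ties counted half (verified against a pair-counting
oracle). The overall AUC pools all instances; it is not the mean of
per-variable AUCs. Per-variable AUCs are reported for every variable with
both classes present; variables structurally missing at a test clinic
simply produce no instances there.

Under the all-evidence strategy, an injected value contaminates the
evidence when the *other* variables of the same plan are scored. This is
deliberate and faithful to the intended clinical use (the reviewer's tool
sees the plan as submitted); it slightly depresses the all-evidence AUC.

The four experiment set-ups are: single-site (train and test in one
clinic), cross-site (train on one, test on each other), two-train-one-test
and pooled. Splits are 80/20 within each clinic before any merging; a
single master seed fans out to named per-stage seeds, and results carry a
manifest sufficient to reproduce them bit-identically.

## Numerical and design choices

* State order is schema order everywhere; no reordering, no ties to break.
* CPT rows must sum to 1 within 1e-6 at load; learned rows are exact to
  machine precision.
* Impossible evidence raises an explicit error from `marginal()`; the
  detector converts it to the smallest representable float with a flag
  (reachable only with hand-loaded networks, since Laplace-learned CPTs
  are strictly positive).
* The splitter allocates per-clinic training counts by largest remainder
  so the overall training size is exactly `round(0.8 n)`.
* `merge_cohorts` unions state vocabularies per variable and namespaces
  plan ids by clinic only when they would collide.
* Whether the historical 80/20 split was stratified is unknowable from the
  outside; stratification was chosen because the multi-site set-ups need
  clinic-balanced test sets.
* Default run sizes for the multi-clinic study are 5 seeds x 2000 plans
  per clinic x 3 clinics, with 5% injection — the package's standard
  protocol, small enough to run on a laptop in under a minute per
  experiment.

## Known limitations

* The all-evidence strategy's advantage over diagnostic-only is marginal
  under the default synthetic generator (the two overall AUCs typically
  agree within ~0.02 and can order either way depending on seeds). In the
  authored ground truth the diagnostic variables strongly determine
  treatment technique, which in turn drives most plan variables, so
  diagnostic evidence is already highly informative. Real clinical data
  show more within-diagnosis practice variation, which is precisely what
  the all-evidence strategy exploits; expect a larger gap there.
* Per-variable AUCs on 5%-injected test sets of a few hundred plans rest
  on a handful of positives per variable and are accordingly noisy.
* The injector covers one error event per plan by default and no
  correlated or compound error scenarios.
* The generator does not model temporal drift, real institutional
  frequency tables, or informative missingness.
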