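"""Multi-clinic experiments: single-site vs cross-site training, and the
two evidence strategies on identical data.

Three synthetic clinics share the network structure but differ in their
CPTs (divergence 1.0 puts the mean row total-variation distance between
clinics near 0.2).  Training in-clinic should beat importing a model from
a divergent clinic; pooled training should come close to the best single
site.  Sizes here are kept small for a quick demonstration.
"""

from rtplanqa import ExperimentConfig, compare_strategies, run_experiment
from rtplanqa.inject import InjectionConfig
from rtplanqa.synthetic import GeneratorConfig

GEN = GeneratorConfig(n_per_clinic=800, divergence=1.0)
INJ = InjectionConfig(rate=0.10)

single = run_experiment(ExperimentConfig(
    setup="single_site", train_clinics=("clinic_a",),
    test_clinics=("clinic_a",), generator=GEN, injection=INJ, seed=5,
))[0]
print(f"single-site  A->A : overall AUC {single.overall_auc:.3f}")

for r in run_experiment(ExperimentConfig(
    setup="cross_site", train_clinics=("clinic_a",),
    test_clinics=("clinic_b", "clinic_c"), generator=GEN, injection=INJ,
    seed=5,
)):
    print(f"cross-site   A->{r.test_clinics[0][-1].upper()} : "
          f"overall AUC {r.overall_auc:.3f}")

pooled = run_experiment(ExperimentConfig(
    setup="pooled",
    train_clinics=("clinic_a", "clinic_b", "clinic_c"),
    test_clinics=("clinic_a", "clinic_b", "clinic_c"),
    generator=GEN, injection=INJ, seed=5,
))[0]
print(f"pooled      all->all: overall AUC {pooled.overall_auc:.3f}")

paired = compare_strategies(ExperimentConfig(
    setup="single_site", train_clinics=("clinic_b",),
    test_clinics=("clinic_b",), generator=GEN, injection=INJ, seed=5,
))
print("\nevidence strategies on identical data (clinic B):")
for mode, results in paired.items():
    print(f"  {mode:<16}: overall AUC {results[0].overall_auc:.3f}")

print(
    "\nIn-clinic training exploits the local practice distribution; a model"
    "\nimported from a divergent clinic degrades, and pooling recovers most"
    "\nof the gap - the cross-site generalization trade-off."
)
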