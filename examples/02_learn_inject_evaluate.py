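"""Single-clinic pipeline: sample, split 80/20, learn by EM, inject 5%
errors, evaluate with ROC/AUC.

This is the in-clinic workflow: the network is trained on historical plans
and validated against the same clinic's held-out plans with simulated
errors embedded at the default 5% rate.
"""

from rtplanqa import (
    EvidenceStrategy,
    InjectionConfig,
    SplitConfig,
    base_network,
    collect_instances,
    default_structure,
    inject_errors,
    learn_em,
    per_variable_auc,
    roc_auc,
    split_cohort,
)
from rtplanqa.synthetic import GeneratorConfig, build_profiles, sample_plans

profile = build_profiles(
    base_network(), GeneratorConfig(n_per_clinic=2000, seed=7, divergence=0.0)
)[0]
cohort = sample_plans(profile, 2000, seed=7)
train, test = split_cohort(cohort, SplitConfig(train_fraction=0.80, seed=7))
print(f"cohort {len(cohort)} plans -> train {len(train)} / test {len(test)}")

network = learn_em(default_structure(), train)
info = network.learn_info
print(f"EM converged in {info['iterations']} iterations "
      f"({info['n_incomplete_rows']} rows had missing values)")

test_injected, records = inject_errors(
    test, config=InjectionConfig(rate=0.05, seed=7)
)
print(f"injected errors into {len({r.plan_id for r in records})} plans "
      f"({len(records)} corrupted values)")

instances, _ = collect_instances(
    network, test_injected, records, EvidenceStrategy("all_but_target")
)
curve = roc_auc(instances)
print(f"\noverall AUC {curve.auc:.3f} "
      f"({curve.n_pos} positives / {curve.n_neg} negatives)")
print("\nper-variable AUC (how well each variable's errors are ranked):")
for var, auc in sorted(per_variable_auc(instances).items(),
                       key=lambda kv: -kv[1]):
    print(f"  {var:<22}{auc:.3f}")
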