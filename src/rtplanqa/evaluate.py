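"""ROC/AUC evaluation of the detector and the four multi-site experiment
set-ups.

Each scored (plan, variable) pair becomes a detection instance whose label
says whether that value was corrupted by the error injector.  Ranking by the
marginal probability (lower = more anomalous) and sweeping the anomaly
threshold over every distinct score yields a ROC curve; the area under it is
the headline discrimination metric, reported per variable and pooled over
all instances.  The experiment set-ups cover training and testing within one
clinic, across clinics, on two clinics against the third, and pooled over
all clinics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .defaults import DIAGNOSTIC_VARIABLES
from .detect import DetectorConfig, EvidenceStrategy, PlanScorer
from .ground_truth import base_network
from .inject import InjectionConfig, InjectionRecord, inject_errors
from .network import BayesianNetwork, LearnConfig, default_structure, learn_em
from .schema import Cohort, SplitConfig, merge_cohorts, split_cohort
from .synthetic import GeneratorConfig, build_profiles, sample_plans

SETUPS = ("single_site", "cross_site", "two_train_one_test", "pooled")


def stage_seed(seed: int, label: str) -> int:
    """Fan one master seed out to named pipeline stages (stable hash)."""
    return zlib.crc32(f"{seed}:{label}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class DetectionInstance:
    plan_id: str
    variable: str
    score: float
    label: int


@dataclass
class ROCCurve:
    points: list[tuple[float, float, float]]  # (threshold, sens, spec)
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(instances: list[DetectionInstance]) -> ROCCurve:
    """Threshold-sweep ROC over the marginal-probability scores.

    A plan variable is called positive when its probability falls below the
    threshold, so the ranking score is the negated probability; tied scores
    follow the Mann-Whitney half-count convention.
    """
    y = np.array([i.label for i in instances])
    p = np.array([i.score for i in instances])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = roc_curve(y, -p)
    points = [
        (float(-t), float(s), float(1.0 - f))
        for t, s, f in zip(thr, tpr, fpr)
    ]
    return ROCCurve(points, float(roc_auc_score(y, -p)), n_pos, n_neg)


def collect_instances(
    network: BayesianNetwork,
    test: Cohort,
    records: list[InjectionRecord],
    strategy: EvidenceStrategy,
    *,
    scorer: PlanScorer | None = None,
) -> tuple[list[DetectionInstance], dict]:
    """Score every plan and label each scored (plan, variable).

    Also reports injection records that never produced an instance (for
    example an error on a variable the detector does not score), rather than
    dropping them silently.
    """
    if scorer is None:
        scorer = PlanScorer(network, DetectorConfig(strategy=strategy))
    injected = {(r.plan_id, r.variable) for r in records}
    instances: list[DetectionInstance] = []
    seen: set[tuple[str, str]] = set()
    for plan in test.plans:
        for s in scorer.score_plan(plan):
            key = (s.plan_id, s.variable)
            seen.add(key)
            instances.append(
                DetectionInstance(s.plan_id, s.variable, s.score,
                                  int(key in injected))
            )
    unmatched = sorted(injected - seen)
    report = {
        "n_instances": len(instances),
        "n_positive": sum(i.label for i in instances),
        "unmatched_records": unmatched,
    }
    return instances, report


def per_variable_auc(
    instances: list[DetectionInstance],
) -> dict[str, float]:
    """AUC per variable; variables with a single class are omitted."""
    by_var: dict[str, list[DetectionInstance]] = {}
    for i in instances:
        by_var.setdefault(i.variable, []).append(i)
    out = {}
    for var, sub in sorted(by_var.items()):
        labels = {i.label for i in sub}
        if labels == {0, 1}:
            out[var] = roc_auc(sub).auc
    return out


@dataclass(frozen=True)
class ExperimentConfig:
    setup: str = "single_site"
    train_clinics: tuple[str, ...] = ("clinic_a",)
    test_clinics: tuple[str, ...] = ("clinic_a",)
    strategy: EvidenceStrategy = field(default_factory=EvidenceStrategy)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    injection: InjectionConfig = field(default_factory=InjectionConfig)
    learn: LearnConfig = field(default_factory=LearnConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    seed: int = 0

    def __post_init__(self):
        if self.setup not in SETUPS:
            raise ValueError(f"unknown setup {self.setup!r}")
        tr, te = set(self.train_clinics), set(self.test_clinics)
        if self.setup == "single_site":
            if len(tr) != 1 or tr != te:
                raise ValueError("single_site needs train == test, one clinic")
        elif self.setup == "cross_site":
            if len(tr) != 1 or tr & te:
                raise ValueError("cross_site needs one train clinic, "
                                 "disjoint test clinics")
        elif self.setup == "two_train_one_test":
            if len(tr) != 2 or len(te) != 1 or tr & te:
                raise ValueError("two_train_one_test needs |train|=2, "
                                 "|test|=1, disjoint")
        else:
            all_c = set(self.generator.clinic_ids)
            if tr != all_c or te != all_c:
                raise ValueError("pooled needs train = test = all clinics")


@dataclass
class ExperimentResult:
    setup: str
    train_clinics: tuple[str, ...]
    test_clinics: tuple[str, ...]
    strategy_mode: str
    per_variable_auc: dict[str, float]
    overall_auc: float
    n_pos: int
    n_neg: int
    manifest: dict


@dataclass
class PreparedWorld:
    """Per-clinic train partitions and error-injected test partitions, with
    the injection ground truth and the seed manifest."""

    train: dict[str, Cohort]
    test: dict[str, Cohort]
    records: dict[str, list[InjectionRecord]]
    manifest: dict


def prepare_world(config: ExperimentConfig) -> PreparedWorld:
    """Generate clinic cohorts, split 80/20 within each clinic, and inject
    errors into each clinic's test partition.  Every stage is seeded from
    ``config.seed`` through named stage seeds."""
    gen = replace(config.generator,
                  seed=stage_seed(config.seed, "profiles"))
    profiles = build_profiles(base_network(), gen)
    train: dict[str, Cohort] = {}
    test: dict[str, Cohort] = {}
    records: dict[str, list[InjectionRecord]] = {}
    seeds: dict[str, int] = {"profiles": gen.seed}
    for profile in profiles:
        c = profile.clinic_id
        s_sample = stage_seed(config.seed, f"sample:{c}")
        s_split = stage_seed(config.seed, f"split:{c}")
        s_inject = stage_seed(config.seed, f"inject:{c}")
        seeds.update({f"sample:{c}": s_sample, f"split:{c}": s_split,
                      f"inject:{c}": s_inject})
        cohort = sample_plans(profile, gen.n_per_clinic, s_sample)
        tr, te = split_cohort(
            cohort, replace(config.split, seed=s_split)
        )
        te_inj, recs = inject_errors(
            te, None, replace(config.injection, seed=s_inject)
        )
        train[c], test[c], records[c] = tr, te_inj, recs
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "setup": config.setup,
        "n_per_clinic": gen.n_per_clinic,
        "divergence": gen.divergence,
        "injection_rate": config.injection.rate,
        "train_fraction": config.split.train_fraction,
    }
    return PreparedWorld(train, test, records, manifest)


def train_network(
    world: PreparedWorld, clinics, learn: LearnConfig
) -> BayesianNetwork:
    cohort = merge_cohorts([world.train[c] for c in clinics])
    return learn_em(default_structure(), cohort, learn)


def evaluate_on(
    network: BayesianNetwork,
    world: PreparedWorld,
    test_clinics,
    strategy: EvidenceStrategy,
) -> tuple[list[DetectionInstance], dict]:
    scorer = PlanScorer(network, DetectorConfig(strategy=strategy))
    instances: list[DetectionInstance] = []
    reports = {}
    for c in test_clinics:
        inst, rep = collect_instances(
            network, world.test[c], world.records[c], strategy, scorer=scorer
        )
        instances.extend(inst)
        reports[c] = rep
    return instances, reports


def run_experiment(config: ExperimentConfig) -> list[ExperimentResult]:
    """Full pipeline for one experiment set-up.

    Returns one result per test clinic for the cross-site set-up (mirroring
    its one-against-each evaluation) and a single pooled result otherwise.
    """
    world = prepare_world(config)
    network = train_network(world, config.train_clinics, config.learn)
    test_groups = (
        [(c,) for c in config.test_clinics]
        if config.setup == "cross_site"
        else [tuple(config.test_clinics)]
    )
    results = []
    for group in test_groups:
        instances, reports = evaluate_on(
            network, world, group, config.strategy
        )
        curve = roc_auc(instances)
        results.append(
            ExperimentResult(
                setup=config.setup,
                train_clinics=tuple(config.train_clinics),
                test_clinics=group,
                strategy_mode=config.strategy.mode,
                per_variable_auc=per_variable_auc(instances),
                overall_auc=curve.auc,
                n_pos=curve.n_pos,
                n_neg=curve.n_neg,
                manifest={**world.manifest, "collect_reports": reports},
            )
        )
    return results


def compare_strategies(
    config: ExperimentConfig,
) -> dict[str, list[ExperimentResult]]:
    """Evaluate the identical world and trained network under both evidence
    strategies (same seeds, same cohorts, same injections)."""
    world = prepare_world(config)
    network = train_network(world, config.train_clinics, config.learn)
    test_groups = (
        [(c,) for c in config.test_clinics]
        if config.setup == "cross_site"
        else [tuple(config.test_clinics)]
    )
    out: dict[str, list[ExperimentResult]] = {}
    for mode in ("diagnostic_only", "all_but_target"):
        strategy = EvidenceStrategy(mode=mode)
        results = []
        for group in test_groups:
            instances, reports = evaluate_on(network, world, group, strategy)
            curve = roc_auc(instances)
            results.append(
                ExperimentResult(
                    config.setup, tuple(config.train_clinics), group, mode,
                    per_variable_auc(instances), curve.auc,
                    curve.n_pos, curve.n_neg,
                    {**world.manifest, "collect_reports": reports},
                )
            )
        out[mode] = results
    return out


def headline_patterns(
    seeds=(0, 1, 2, 3, 4),
    n_per_clinic: int = 2000,
    divergence: float = 1.0,
    learn: LearnConfig = LearnConfig(),
) -> dict:
    """The study's three qualitative findings, measured on synthetic
    multi-clinic data and averaged over seeds:

    * training and testing within one clinic beats training on one clinic
      and testing on another;
    * instantiating all observed variables is at least as discriminative as
      instantiating the diagnostic variables only;
    * pooled training over all clinics comes close to the best single-site
      performance.
    """
    clinics = ("clinic_a", "clinic_b", "clinic_c")
    single, cross, pooled, best_single = [], [], [], []
    diag, allev = [], []
    for seed in seeds:
        cfg = ExperimentConfig(
            setup="pooled", train_clinics=clinics, test_clinics=clinics,
            generator=GeneratorConfig(
                clinic_ids=clinics, n_per_clinic=n_per_clinic,
                divergence=divergence,
            ),
            learn=learn, seed=seed,
        )
        world = prepare_world(cfg)
        nets = {c: train_network(world, (c,), learn) for c in clinics}
        pooled_net = train_network(world, clinics, learn)
        all_ev = EvidenceStrategy("all_but_target")
        diag_ev = EvidenceStrategy("diagnostic_only")
        single_aucs = {}
        for c in clinics:
            inst, _ = evaluate_on(nets[c], world, (c,), all_ev)
            single_aucs[c] = roc_auc(inst).auc
            inst_d, _ = evaluate_on(nets[c], world, (c,), diag_ev)
            diag.append(roc_auc(inst_d).auc)
            allev.append(single_aucs[c])
        single.extend(single_aucs.values())
        best_single.append(max(single_aucs.values()))
        for c_train in clinics:
            for c_test in clinics:
                if c_test == c_train:
                    continue
                inst, _ = evaluate_on(nets[c_train], world, (c_test,), all_ev)
                cross.append(roc_auc(inst).auc)
        inst, _ = evaluate_on(pooled_net, world, clinics, all_ev)
        pooled.append(roc_auc(inst).auc)
    return {
        "single_site_auc": float(np.mean(single)),
        "cross_site_auc": float(np.mean(cross)),
        "diagnostic_only_auc": float(np.mean(diag)),
        "all_but_target_auc": float(np.mean(allev)),
        "pooled_auc": float(np.mean(pooled)),
        "best_single_site_auc": float(np.mean(best_single)),
        "n_seeds": len(seeds),
        "n_per_clinic": n_per_clinic,
        "divergence": divergence,
    }


def results_to_frame(results: list[ExperimentResult]):
    """Variable-by-strategy AUC table shaped like the per-variable report
    tables of a multi-site validation."""
    import pandas as pd

    rows = []
    for r in results:
        for var, auc in r.per_variable_auc.items():
            rows.append(
                {
                    "setup": r.setup,
                    "train": "+".join(r.train_clinics),
                    "test": "+".join(r.test_clinics),
                    "strategy": r.strategy_mode,
                    "variable": var,
                    "auc": auc,
                }
            )
        rows.append(
            {
                "setup": r.setup,
                "train": "+".join(r.train_clinics),
                "test": "+".join(r.test_clinics),
                "strategy": r.strategy_mode,
                "variable": "overall",
                "auc": r.overall_auc,
            }
        )
    return pd.DataFrame(
        rows, columns=["setup", "train", "test", "strategy", "variable", "auc"]
    )
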