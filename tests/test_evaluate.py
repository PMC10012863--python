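"""Evaluation harness: ROC/AUC against a pair-counting oracle, instance
collection, and the four experiment set-ups."""

import numpy as np
import pytest

from rtplanqa.detect import EvidenceStrategy
from rtplanqa.evaluate import (
    DetectionInstance,
    ExperimentConfig,
    collect_instances,
    compare_strategies,
    per_variable_auc,
    roc_auc,
    run_experiment,
)
from rtplanqa.ground_truth import base_network
from rtplanqa.inject import ErrorSpec, InjectionConfig, InjectionRecord, inject_errors
from rtplanqa.network import learn_em
from rtplanqa.synthetic import ClinicProfile, GeneratorConfig, sample_plans

from _oracles import pair_count_auc


def _inst(scores, labels):
    return [
        DetectionInstance(f"p{i}", "v", s, l)
        for i, (s, l) in enumerate(zip(scores, labels))
    ]


class TestROC:
    def test_perfect_separation(self):
        inst = _inst([0.001] * 5 + [0.9] * 5, [1] * 5 + [0] * 5)
        assert roc_auc(inst).auc == 1.0

    def test_all_ties_give_half(self):
        inst = _inst([0.3] * 10, [1] * 3 + [0] * 7)
        assert roc_auc(inst).auc == 0.5

    def test_hand_listed_instances_match_pair_counting(self):
        scores = [0.01, 0.20, 0.05, 0.80, 0.05, 0.30, 0.02, 0.55, 0.05, 0.90]
        labels = [1, 0, 1, 0, 0, 1, 1, 0, 1, 0]
        inst = _inst(scores, labels)
        assert roc_auc(inst).auc == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )

    def test_random_lists_match_pair_counting(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            inst = _inst(scores, labels)
            assert roc_auc(inst).auc == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_inst([0.1, 0.2], [0, 0]))

    def test_sensitivity_monotone_along_sweep(self):
        rng = np.random.default_rng(8)
        scores = rng.random(100)
        labels = (scores < 0.4).astype(int) ^ (rng.random(100) < 0.1)
        curve = roc_auc(_inst(scores, labels.astype(int)))
        sens = [p[1] for p in curve.points]
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))


@pytest.fixture(scope="module")
def small_world():
    base = base_network()
    cohort = sample_plans(ClinicProfile("clinic_a", base, missingness={}),
                          300, 55)
    net = learn_em(base.structure, cohort)
    return base, net, cohort


class TestCollectInstances:
    def test_zero_injections_all_negative(self, small_world):
        _, net, cohort = small_world
        inst, report = collect_instances(
            net, cohort, [], EvidenceStrategy("all_but_target")
        )
        assert report["n_positive"] == 0
        assert all(i.label == 0 for i in inst)

    def test_single_variable_events_give_one_positive_each(self, small_world):
        _, net, cohort = small_world
        specs = [ErrorSpec("setup", "table_angle", "shift-angle-bin")]
        injected, records = inject_errors(
            cohort, specs, InjectionConfig(rate=0.1, seed=4,
                                           category_weights={"setup": 1.0}),
        )
        inst, report = collect_instances(
            net, injected, records, EvidenceStrategy("all_but_target")
        )
        assert report["n_positive"] == len(records) == 30
        assert report["unmatched_records"] == []

    def test_record_on_unscored_variable_reported(self, small_world):
        _, net, cohort = small_world
        phantom = [InjectionRecord("no-such-plan", "ssd", "[90,100)",
                                   "[60,70)", "planning")]
        _, report = collect_instances(
            net, cohort, phantom, EvidenceStrategy("all_but_target")
        )
        assert report["unmatched_records"] == [("no-such-plan", "ssd")]

    def test_instance_scores_equal_detector_scores(self, small_world):
        from rtplanqa.detect import DetectorConfig, PlanScorer

        _, net, cohort = small_world
        inst, _ = collect_instances(
            net, cohort, [], EvidenceStrategy("all_but_target")
        )
        scorer = PlanScorer(net, DetectorConfig())
        plan = cohort.plans[0]
        direct = {s.variable: s.score for s in scorer.score_plan(plan)}
        for i in inst:
            if i.plan_id == plan.plan_id:
                assert i.score == direct[i.variable]


def _tiny_config(**kw):
    defaults = dict(
        setup="single_site",
        train_clinics=("clinic_a",),
        test_clinics=("clinic_a",),
        generator=GeneratorConfig(n_per_clinic=300, divergence=1.0),
        injection=InjectionConfig(rate=0.2),
        seed=13,
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


class TestExperiments:
    def test_single_site_wiring(self):
        results = run_experiment(_tiny_config())
        assert len(results) == 1
        r = results[0]
        assert r.test_clinics == ("clinic_a",)
        assert 0.0 <= r.overall_auc <= 1.0
        assert r.per_variable_auc
        # overall pools instances rather than averaging per-variable AUCs
        assert r.overall_auc != pytest.approx(
            np.mean(list(r.per_variable_auc.values())), abs=1e-6
        )

    def test_cross_site_returns_one_result_per_test_clinic(self):
        results = run_experiment(_tiny_config(
            setup="cross_site",
            test_clinics=("clinic_b", "clinic_c"),
        ))
        assert [r.test_clinics for r in results] == [
            ("clinic_b",), ("clinic_c",)
        ]

    def test_setup_consistency_enforced(self):
        with pytest.raises(ValueError):
            _tiny_config(setup="cross_site", test_clinics=("clinic_a",))
        with pytest.raises(ValueError):
            _tiny_config(setup="two_train_one_test",
                         train_clinics=("clinic_a",),
                         test_clinics=("clinic_b",))

    def test_deterministic_manifests(self):
        a = run_experiment(_tiny_config())[0]
        b = run_experiment(_tiny_config())[0]
        assert a.manifest == b.manifest
        assert a.overall_auc == b.overall_auc
        assert a.per_variable_auc == b.per_variable_auc

    def test_structurally_missing_variables_absent_from_instances(self):
        results = run_experiment(_tiny_config(
            setup="cross_site",
            test_clinics=("clinic_c",),
        ))
        assert "wedge" not in results[0].per_variable_auc
        assert "tolerance_table" not in results[0].per_variable_auc


class TestCompareStrategies:
    def test_identical_worlds_and_paired_outputs(self):
        paired = compare_strategies(_tiny_config())
        assert set(paired) == {"diagnostic_only", "all_but_target"}
        ra = paired["diagnostic_only"][0]
        rb = paired["all_but_target"][0]
        assert ra.manifest["stage_seeds"] == rb.manifest["stage_seeds"]
        assert ra.n_pos == rb.n_pos and ra.n_neg == rb.n_neg

    def test_no_nondiagnostic_neighbours_means_no_strategy_delta(self):
        """A target d-separated from everything but the diagnostic set gets
        the same score under both strategies (checked by computation)."""
        from rtplanqa.detect import score_variable
        from rtplanqa.network import CPT, BayesianNetwork, NetworkStructure
        from rtplanqa.schema import PlanRecord, VariableSpec

        structure = NetworkStructure(
            ("tumor_site", "T", "X"), (("tumor_site", "T"),)
        )
        schema = [
            VariableSpec("tumor_site", "diagnostic", ("lung", "breast")),
            VariableSpec("T", "treatment_planning", ("t0", "t1")),
            VariableSpec("X", "treatment_planning", ("x0", "x1")),
        ]
        cpts = {
            "tumor_site": CPT("tumor_site", (), np.array([0.6, 0.4])),
            "T": CPT("T", ("tumor_site",),
                     np.array([[0.9, 0.1], [0.3, 0.7]])),
            "X": CPT("X", (), np.array([0.5, 0.5])),
        }
        net = BayesianNetwork(structure, cpts, schema)
        plan = PlanRecord("p", "c",
                          {"tumor_site": "lung", "T": "t1", "X": "x0"})
        diag = score_variable(
            net, plan, "T",
            EvidenceStrategy("diagnostic_only", ("tumor_site",)),
        )
        alle = score_variable(net, plan, "T",
                              EvidenceStrategy("all_but_target"))
        assert diag.score == pytest.approx(alle.score, abs=1e-12)


def test_per_variable_auc_skips_single_class():
    inst = [
        DetectionInstance("p1", "a", 0.1, 1),
        DetectionInstance("p2", "a", 0.9, 0),
        DetectionInstance("p3", "b", 0.5, 0),
    ]
    table = per_variable_auc(inst)
    assert "a" in table and "b" not in table
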