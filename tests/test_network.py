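"""Bayesian-network core: structure validation, exact inference against
enumeration, EM learning against counting/enumeration oracles, and
serialization round trips."""

import numpy as np
import pytest

from rtplanqa.network import (
    CPT,
    BayesianNetwork,
    ImpossibleEvidenceError,
    LearnConfig,
    NetworkStructure,
    StructureError,
    default_structure,
    joint_probability,
    learn_em,
    load_network,
    load_structure,
    marginal,
    save_network,
    save_structure,
    validate_structure,
)
from rtplanqa.schema import VariableSpec

from _oracles import (
    counting_cpts,
    em_by_enumeration,
    enumerate_marginal,
    random_network,
)


class TestStructure:
    def test_default_structure_counts(self):
        s = default_structure()
        report = validate_structure(s.nodes, s.edges)
        assert report["valid"]
        assert report["n_nodes"] == 24
        assert report["n_edges"] == 41
        assert report["orphans"] == []

    def test_cycle_detected_and_named(self):
        with pytest.raises(StructureError) as err:
            validate_structure(["A", "B"], [("A", "B"), ("B", "A")])
        assert "A" in str(err.value) and "B" in str(err.value)

    def test_single_node_valid(self):
        report = validate_structure(["X"], [])
        assert report["valid"] and report["n_nodes"] == 1

    def test_undeclared_edge_endpoint(self):
        with pytest.raises(StructureError):
            NetworkStructure(("A",), (("A", "B"),))


def _independent_pair():
    structure = NetworkStructure(("X", "Y"), ())
    schema = [
        VariableSpec("X", "treatment_planning", ("x0", "x1")),
        VariableSpec("Y", "treatment_planning", ("y0", "y1")),
    ]
    cpts = {
        "X": CPT("X", (), np.array([0.5, 0.5])),
        "Y": CPT("Y", (), np.array([0.5, 0.5])),
    }
    return BayesianNetwork(structure, cpts, schema)


class TestJointProbability:
    def test_independent_uniform_binaries(self):
        net = _independent_pair()
        for x in ("x0", "x1"):
            for y in ("y0", "y1"):
                assert joint_probability(net, {"X": x, "Y": y}) == 0.25

    def test_degenerate_chain_probability_one(self):
        structure = NetworkStructure(("A", "B"), (("A", "B"),))
        schema = [
            VariableSpec("A", "diagnostic", ("a", "a'")),
            VariableSpec("B", "treatment_planning", ("b", "b'")),
        ]
        cpts = {
            "A": CPT("A", (), np.array([1.0, 0.0])),
            "B": CPT("B", ("A",), np.array([[1.0, 0.0], [0.5, 0.5]])),
        }
        net = BayesianNetwork(structure, cpts, schema)
        assert joint_probability(net, {"A": "a", "B": "b"}) == 1.0

    def test_incomplete_assignment_rejected(self):
        net = _independent_pair()
        with pytest.raises(Exception):
            joint_probability(net, {"X": "x0"})

    def test_matches_enumerated_joint_on_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = random_network(rng, max_nodes=4)
            states = {v.name: v.states for v in net.schema}
            total = 0.0
            import itertools

            for combo in itertools.product(
                *(range(len(states[n])) for n in net.structure.nodes)
            ):
                assign = {
                    n: states[n][i]
                    for n, i in zip(net.structure.nodes, combo)
                }
                total += joint_probability(net, assign)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestMarginal:
    def test_single_uniform_node_no_evidence(self):
        net = _independent_pair()
        np.testing.assert_allclose(marginal(net, {}, "X"), [0.5, 0.5])

    def test_evidence_on_parent_returns_cpt_row(self, chain_network):
        post = marginal(chain_network, {"A": "a1"}, "B")
        np.testing.assert_allclose(post, [0.2, 0.8], atol=1e-12)

    def test_matches_enumeration_on_random_networks(self):
        rng = np.random.default_rng(23)
        worst = 0.0
        for _ in range(25):
            net = random_network(rng)
            nodes = list(net.structure.nodes)
            k = int(rng.integers(0, len(nodes)))
            ev_nodes = list(rng.choice(nodes, size=k, replace=False))
            target = next(n for n in nodes if n not in ev_nodes)
            evidence = {
                n: net.spec(n).states[int(rng.integers(net.card(n)))]
                for n in ev_nodes
            }
            try:
                expect = enumerate_marginal(net, evidence, target)
            except ValueError:
                continue
            got = marginal(net, evidence, target)
            worst = max(worst, float(np.abs(got - expect).max()))
        assert worst < 1e-9

    def test_impossible_evidence_raises(self):
        structure = NetworkStructure(("A", "B"), (("A", "B"),))
        schema = [
            VariableSpec("A", "diagnostic", ("a", "a'")),
            VariableSpec("B", "treatment_planning", ("b", "b'")),
        ]
        cpts = {
            "A": CPT("A", (), np.array([1.0, 0.0])),
            "B": CPT("B", ("A",), np.array([[1.0, 0.0], [0.5, 0.5]])),
        }
        net = BayesianNetwork(structure, cpts, schema)
        with pytest.raises(ImpossibleEvidenceError):
            marginal(net, {"A": "a'"}, "B")

    def test_target_in_evidence_rejected(self, chain_network):
        with pytest.raises(Exception):
            marginal(chain_network, {"B": "b0"}, "B")


def _three_node():
    structure = NetworkStructure(
        ("A", "B", "C"), (("A", "B"), ("A", "C"))
    )
    schema = [
        VariableSpec("A", "diagnostic", ("a0", "a1")),
        VariableSpec("B", "treatment_planning", ("b0", "b1", "b2")),
        VariableSpec("C", "treatment_planning", ("c0", "c1")),
    ]
    return structure, schema


def _ground_truth_three_node():
    structure, schema = _three_node()
    cpts = {
        "A": CPT("A", (), np.array([0.6, 0.4])),
        "B": CPT("B", ("A",),
                 np.array([[0.5, 0.3, 0.2], [0.1, 0.2, 0.7]])),
        "C": CPT("C", ("A",), np.array([[0.8, 0.2], [0.3, 0.7]])),
    }
    return BayesianNetwork(structure, cpts, schema)


class TestLearnEM:
    def test_complete_data_matches_counting_closed_form(
        self, toy_cohort_factory
    ):
        net = _ground_truth_three_node()
        cohort = toy_cohort_factory(net, 50, seed=5)
        learned = learn_em(net.structure, cohort)
        expect = counting_cpts(net.structure, cohort)
        for node in net.structure.nodes:
            np.testing.assert_allclose(
                learned.cpts[node].values, expect[node], atol=1e-9
            )
        assert learned.learn_info["n_incomplete_rows"] == 0

    def test_zero_rows_gives_uniform_cpts(self):
        net = _ground_truth_three_node()
        from rtplanqa.schema import Cohort

        learned = learn_em(net.structure, Cohort([], net.schema))
        for node in net.structure.nodes:
            r = net.card(node)
            np.testing.assert_allclose(
                learned.cpts[node].values, 1.0 / r, atol=1e-12
            )

    def test_missing_data_matches_enumeration_em(self, toy_cohort_factory):
        net = _ground_truth_three_node()
        cohort = toy_cohort_factory(net, 20, seed=9, missing_rate=0.5)
        iters = 5
        learned = learn_em(
            net.structure, cohort,
            LearnConfig(convergence_threshold=1e-300, max_iterations=iters),
        )
        expect = em_by_enumeration(net.structure, cohort, iters)
        for node in net.structure.nodes:
            np.testing.assert_allclose(
                learned.cpts[node].values, expect[node], atol=1e-6
            )

    def test_penalized_loglik_nondecreasing(self, toy_cohort_factory):
        net = _ground_truth_three_node()
        cohort = toy_cohort_factory(net, 60, seed=2, missing_rate=0.35)
        learned = learn_em(
            net.structure, cohort,
            LearnConfig(convergence_threshold=1e-12, max_iterations=40),
        )
        trace = learned.learn_info["penalized_loglik_trace"]
        assert len(trace) > 2
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()

    def test_laplace_strict_positivity(self, toy_cohort_factory):
        net = _ground_truth_three_node()
        cohort = toy_cohort_factory(net, 30, seed=1)
        learned = learn_em(net.structure, cohort)
        for node in net.structure.nodes:
            assert (learned.cpts[node].values > 0).all()
        # hence no observed evidence combination is impossible
        for a in ("a0", "a1"):
            for b in ("b0", "b1", "b2"):
                post = marginal(learned, {"A": a, "B": b}, "C")
                assert post.sum() == pytest.approx(1.0)

    def test_parameter_recovery_improves_with_n(self, toy_cohort_factory):
        net = _ground_truth_three_node()
        tvs = []
        for n in (200, 2000):
            cohort = toy_cohort_factory(net, n, seed=7)
            learned = learn_em(net.structure, cohort)
            tv = []
            for node in net.structure.nodes:
                a = learned.cpts[node].values
                b = net.cpts[node].values
                tv.append(0.5 * np.abs(a - b).sum(axis=-1).mean())
            tvs.append(float(np.mean(tv)))
        assert tvs[1] < tvs[0]


class TestSerialization:
    def test_xmlbif_round_trip_full_precision(self, tmp_path,
                                              toy_cohort_factory):
        net = _ground_truth_three_node()
        path = tmp_path / "net.xmlbif"
        save_network(net, path)
        loaded = load_network(path)
        assert loaded.structure == net.structure
        for node in net.structure.nodes:
            np.testing.assert_array_equal(
                loaded.cpts[node].values, net.cpts[node].values
            )
            assert loaded.spec(node).category == net.spec(node).category

    def test_hand_written_two_node_file(self, tmp_path):
        path = tmp_path / "hand.xmlbif"
        path.write_text(
            """<?xml version="1.0"?>
<BIF VERSION="0.3"><NETWORK><NAME>toy</NAME>
<VARIABLE TYPE="nature"><NAME>rain</NAME>
<OUTCOME>no</OUTCOME><OUTCOME>yes</OUTCOME></VARIABLE>
<VARIABLE TYPE="nature"><NAME>wet</NAME>
<OUTCOME>no</OUTCOME><OUTCOME>yes</OUTCOME></VARIABLE>
<DEFINITION><FOR>rain</FOR><TABLE>0.8 0.2</TABLE></DEFINITION>
<DEFINITION><FOR>wet</FOR><GIVEN>rain</GIVEN>
<TABLE>0.9 0.1 0.05 0.95</TABLE></DEFINITION>
</NETWORK></BIF>"""
        )
        net = load_network(path)
        assert net.structure.edges == (("rain", "wet"),)
        np.testing.assert_allclose(
            net.cpts["wet"].values, [[0.9, 0.1], [0.05, 0.95]]
        )
        np.testing.assert_allclose(marginal(net, {}, "rain"), [0.8, 0.2])

    def test_unnormalized_row_rejected(self, tmp_path):
        path = tmp_path / "bad.xmlbif"
        path.write_text(
            """<?xml version="1.0"?>
<BIF VERSION="0.3"><NETWORK><NAME>bad</NAME>
<VARIABLE TYPE="nature"><NAME>x</NAME>
<OUTCOME>a</OUTCOME><OUTCOME>b</OUTCOME></VARIABLE>
<DEFINITION><FOR>x</FOR><TABLE>0.5 0.4</TABLE></DEFINITION>
</NETWORK></BIF>"""
        )
        with pytest.raises(ValueError, match="sum"):
            load_network(path)

    def test_structure_text_round_trip(self, tmp_path):
        s = default_structure()
        path = tmp_path / "structure.txt"
        save_structure(s, path)
        loaded = load_structure(path)
        assert set(loaded.nodes) == set(s.nodes)
        assert set(loaded.edges) == set(s.edges)
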