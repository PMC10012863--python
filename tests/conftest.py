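import numpy as np
import pytest

from rtplanqa.network import CPT, BayesianNetwork, NetworkStructure
from rtplanqa.schema import Cohort, PlanRecord, VariableSpec


@pytest.fixture
def chain_network():
    """A -> B with deterministic-ish CPTs, plus the uniform isolated C."""
    structure = NetworkStructure(("A", "B", "C"), (("A", "B"),))
    schema = [
        VariableSpec("A", "diagnostic", ("a0", "a1")),
        VariableSpec("B", "treatment_planning", ("b0", "b1")),
        VariableSpec("C", "treatment_planning", ("c0", "c1")),
    ]
    cpts = {
        "A": CPT("A", (), np.array([0.7, 0.3])),
        "B": CPT("B", ("A",), np.array([[0.9, 0.1], [0.2, 0.8]])),
        "C": CPT("C", (), np.array([0.5, 0.5])),
    }
    return BayesianNetwork(structure, cpts, schema)


@pytest.fixture
def toy_cohort_factory():
    """Sampled cohorts from a given network, optionally masked at random."""

    def make(network, n, seed=0, missing_rate=0.0, clinic="clinic_t"):
        from rtplanqa.network import sample_codes

        rng = np.random.default_rng(seed)
        codes = sample_codes(network, n, rng)
        states = {v.name: v.states for v in network.schema}
        nodes = list(network.structure.nodes)
        plans = []
        for i in range(n):
            assignments = {}
            for j, node in enumerate(nodes):
                if missing_rate and rng.random() < missing_rate:
                    continue
                assignments[node] = states[node][codes[i, j]]
            plans.append(PlanRecord(f"p{i:05d}", clinic, assignments))
        return Cohort(plans, list(network.schema))

    return make
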