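"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's factor/elimination machinery: joint
distributions are built by enumerating complete assignments, EM by
enumerating every completion of every partial record, and AUC by counting
concordant/discordant pairs.
"""

from __future__ import annotations

import itertools

import numpy as np

from rtplanqa.network import BayesianNetwork, NetworkStructure
from rtplanqa.schema import Cohort, VariableSpec


def enumerate_marginal(
    network: BayesianNetwork, evidence: dict[str, str], target: str
) -> np.ndarray:
    """P(target | evidence) by summing the fully enumerated joint."""
    nodes = list(network.structure.nodes)
    states = {v.name: v.states for v in network.schema}
    out = np.zeros(len(states[target]))
    for combo in itertools.product(*(range(len(states[n])) for n in nodes)):
        assign = {n: states[n][i] for n, i in zip(nodes, combo)}
        if any(assign[v] != s for v, s in evidence.items()):
            continue
        p = 1.0
        for n in nodes:
            cpt = network.cpts[n]
            idx = tuple(
                states[par].index(assign[par]) for par in cpt.parents
            ) + (states[n].index(assign[n]),)
            p *= float(cpt.values[idx])
        out[states[target].index(assign[target])] += p
    z = out.sum()
    if z <= 0:
        raise ValueError("evidence has zero probability")
    return out / z


def counting_cpts(
    structure: NetworkStructure, cohort: Cohort
) -> dict[str, np.ndarray]:
    """Closed-form Laplace-smoothed CPTs from complete-family counting:
    theta = (N + 1/q) / (N_parent + r/q)."""
    states = {v.name: v.states for v in cohort.schema}
    out = {}
    for node in structure.nodes:
        parents = structure.parents(node)
        dims = tuple(len(states[p]) for p in parents) + (len(states[node]),)
        counts = np.zeros(dims)
        for plan in cohort.plans:
            if node not in plan.assignments:
                continue
            if any(p not in plan.assignments for p in parents):
                continue
            idx = tuple(
                states[p].index(plan.assignments[p]) for p in parents
            ) + (states[node].index(plan.assignments[node]),)
            counts[idx] += 1
        q = int(np.prod(dims[:-1]))
        r = dims[-1]
        alpha = 1.0 / q
        out[node] = (counts + alpha) / (
            counts.sum(axis=-1, keepdims=True) + r * alpha
        )
    return out


def em_by_enumeration(
    structure: NetworkStructure,
    cohort: Cohort,
    n_iterations: int,
) -> dict[str, np.ndarray]:
    """EM that enumerates all completions of each partial record.

    Initialization matches the package's available-case start so that the
    two trajectories are comparable iteration by iteration.
    """
    states = {v.name: v.states for v in cohort.schema}
    nodes = list(structure.nodes)
    parents = {n: structure.parents(n) for n in nodes}
    dims = {
        n: tuple(len(states[p]) for p in parents[n]) + (len(states[n]),)
        for n in nodes
    }
    alpha = {n: 1.0 / int(np.prod(dims[n][:-1])) for n in nodes}

    def m_step(counts):
        theta = {}
        for n in nodes:
            a, r = alpha[n], dims[n][-1]
            theta[n] = (counts[n] + a) / (
                counts[n].sum(axis=-1, keepdims=True) + r * a
            )
        return theta

    theta = counting_cpts(structure, cohort)  # available-case init

    def completions(plan):
        missing = [n for n in nodes if n not in plan.assignments]
        for combo in itertools.product(
            *(range(len(states[m])) for m in missing)
        ):
            full = dict(plan.assignments)
            for m, i in zip(missing, combo):
                full[m] = states[m][i]
            yield full

    def joint(full, theta):
        p = 1.0
        for n in nodes:
            idx = tuple(
                states[par].index(full[par]) for par in parents[n]
            ) + (states[n].index(full[n]),)
            p *= float(theta[n][idx])
        return p

    for _ in range(n_iterations):
        counts = {n: np.zeros(dims[n]) for n in nodes}
        for plan in cohort.plans:
            comps = list(completions(plan))
            weights = np.array([joint(f, theta) for f in comps])
            weights = weights / weights.sum()
            for full, w in zip(comps, weights):
                for n in nodes:
                    idx = tuple(
                        states[par].index(full[par]) for par in parents[n]
                    ) + (states[n].index(full[n]),)
                    counts[n][idx] += w
        theta = m_step(counts)
    return theta


def pair_count_auc(scores, labels) -> float:
    """Mann-Whitney AUC with the ties-half convention; positives are ranked
    by LOW score (low marginal probability = anomalous)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        total += float(np.sum(p < neg)) + 0.5 * float(np.sum(p == neg))
    return total / (len(pos) * len(neg))


def random_network(
    rng: np.random.Generator, max_nodes: int = 6, max_states: int = 4
) -> BayesianNetwork:
    """A random small DAG with Dirichlet(1) CPT rows."""
    from rtplanqa.network import CPT

    n = int(rng.integers(2, max_nodes + 1))
    names = [f"v{i}" for i in range(n)]
    cards = [int(rng.integers(2, max_states + 1)) for _ in range(n)]
    edges = []
    for j in range(n):
        for i in range(j):
            if rng.random() < 0.4:
                edges.append((names[i], names[j]))
    structure = NetworkStructure(tuple(names), tuple(edges))
    schema = [
        VariableSpec(
            names[i], "treatment_planning",
            tuple(f"s{k}" for k in range(cards[i])),
        )
        for i in range(n)
    ]
    cpts = {}
    for i, name in enumerate(names):
        pars = structure.parents(name)
        shape = tuple(cards[names.index(p)] for p in pars) + (cards[i],)
        flat = rng.dirichlet(np.ones(cards[i]), size=int(np.prod(shape[:-1])))
        cpts[name] = CPT(name, pars, flat.reshape(shape))
    return BayesianNetwork(structure, cpts, schema)
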