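"""Discrete Bayesian network: structure, CPTs, exact inference, EM learning.

The network is a DAG over the discrete plan variables; its joint distribution
factorizes as the product of per-node conditional probability tables (CPTs).
Inference is exact (variable elimination); parameters are learned by
expectation-maximization with a Laplace prior whose pseudocount per CPT cell
is the multiplicative inverse of the node's number of parent-state
combinations, so no learned probability is ever exactly zero.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .schema import CATEGORIES, Cohort, SchemaError, VariableSpec


class StructureError(ValueError):
    """Raised for cyclic or otherwise invalid network structures."""


class ImpossibleEvidenceError(ValueError):
    """Raised when the queried evidence has probability zero under the model."""


# ---------------------------------------------------------------------------
# Factors and variable elimination


class Factor:
    """A non-negative table over a tuple of discrete variables."""

    __slots__ = ("scope", "values")

    def __init__(self, scope: tuple[str, ...], values: np.ndarray):
        self.scope = tuple(scope)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != len(self.scope):
            raise ValueError("factor rank does not match scope")

    def _expand(self, scope: tuple[str, ...]) -> np.ndarray:
        perm = [self.scope.index(v) for v in scope if v in self.scope]
        vals = np.transpose(self.values, perm)
        shape = []
        it = iter(vals.shape)
        for v in scope:
            shape.append(next(it) if v in self.scope else 1)
        return vals.reshape(shape)

    def multiply(self, other: "Factor") -> "Factor":
        scope = self.scope + tuple(v for v in other.scope if v not in self.scope)
        return Factor(scope, self._expand(scope) * other._expand(scope))

    def reduce(self, evidence: dict[str, int]) -> "Factor":
        idx = tuple(
            evidence[v] if v in evidence else slice(None) for v in self.scope
        )
        scope = tuple(v for v in self.scope if v not in evidence)
        return Factor(scope, self.values[idx])

    def marginalize_out(self, var: str) -> "Factor":
        ax = self.scope.index(var)
        return Factor(
            self.scope[:ax] + self.scope[ax + 1 :], self.values.sum(axis=ax)
        )

    def marginal_onto(self, order: tuple[str, ...]) -> "Factor":
        f = self
        for v in self.scope:
            if v not in order:
                f = f.marginalize_out(v)
        perm = [f.scope.index(v) for v in order]
        return Factor(tuple(order), np.transpose(f.values, perm))

    def sum(self) -> float:
        return float(self.values.sum())


def _eliminate(factors: list[Factor], elim: list[str]) -> list[Factor]:
    """Sum-product variable elimination with a greedy smallest-factor order."""
    factors = list(factors)
    remaining = set(elim)

    def elim_cost(v: str) -> int:
        scope: set[str] = set()
        card: dict[str, int] = {}
        for f in factors:
            if v in f.scope:
                scope |= set(f.scope)
                for u, c in zip(f.scope, f.values.shape):
                    card[u] = c
        size = 1
        for u in scope:
            size *= card[u]
        return size

    while remaining:
        v = min(sorted(remaining), key=elim_cost)
        remaining.discard(v)
        related = [f for f in factors if v in f.scope]
        factors = [f for f in factors if v not in f.scope]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        factors.append(prod.marginalize_out(v))
    return factors


# ---------------------------------------------------------------------------
# Structure


@dataclass(frozen=True)
class NetworkStructure:
    """DAG over named variables."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        declared = set(self.nodes)
        for a, b in self.edges:
            if a not in declared or b not in declared:
                raise StructureError(f"edge {a}->{b} references undeclared node")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise StructureError(f"structure contains a cycle: {cyc}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        order = {n: i for i, n in enumerate(self.nodes)}
        ps = [a for a, b in self.edges if b == node]
        return tuple(sorted(set(ps), key=order.__getitem__))

    def children(self, node: str) -> tuple[str, ...]:
        order = {n: i for i, n in enumerate(self.nodes)}
        cs = [b for a, b in self.edges if a == node]
        return tuple(sorted(set(cs), key=order.__getitem__))

    def topological_order(self) -> list[str]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return list(nx.lexicographical_topological_sort(
            self.graph(), key=order.__getitem__))


def validate_structure(
    nodes, edges, *, raise_on_cycle: bool = True
) -> dict:
    """Check a candidate structure and report node/edge counts, acyclicity
    and orphan (fully disconnected) nodes."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    acyclic = nx.is_directed_acyclic_graph(g)
    cycle = None
    if not acyclic:
        cycle = [(a, b) for a, b, *_ in nx.find_cycle(g)]
        if raise_on_cycle:
            involved = sorted({n for e in cycle for n in e})
            raise StructureError(f"cycle through nodes {involved}")
    orphans = [n for n in g.nodes if g.degree(n) == 0]
    return {
        "valid": acyclic,
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "orphans": orphans,
        "cycle": cycle,
    }


def default_structure() -> NetworkStructure:
    """The shipped 24-node, 41-edge plan-review structure."""
    from .defaults import DEFAULT_EDGES, default_schema

    nodes = tuple(v.name for v in default_schema())
    s = NetworkStructure(nodes, DEFAULT_EDGES)
    report = validate_structure(s.nodes, s.edges)
    assert report["n_nodes"] == 24 and report["n_edges"] == 41
    return s


# ---------------------------------------------------------------------------
# The network proper


@dataclass
class CPT:
    """P(node | parents): array of shape (*parent cardinalities, node states)."""

    node: str
    parents: tuple[str, ...]
    values: np.ndarray

    def validate(self, atol: float = 1e-9) -> None:
        if (self.values < 0).any():
            raise ValueError(f"{self.node}: negative probability")
        sums = self.values.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=max(atol, 1e-6)):
            bad = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"{self.node}: CPT rows must sum to 1 (max deviation {bad:.3g})"
            )


@dataclass
class BayesianNetwork:
    structure: NetworkStructure
    cpts: dict[str, CPT]
    schema: list[VariableSpec]
    learn_info: dict = field(default_factory=dict)

    def __post_init__(self):
        by_name = {v.name: v for v in self.schema}
        for node in self.structure.nodes:
            if node not in by_name:
                raise SchemaError(f"no VariableSpec for node {node}")
            cpt = self.cpts[node]
            if cpt.parents != self.structure.parents(node):
                raise StructureError(
                    f"{node}: CPT parents {cpt.parents} do not match structure"
                )
            expect = tuple(
                len(by_name[p].states) for p in cpt.parents
            ) + (len(by_name[node].states),)
            if cpt.values.shape != expect:
                raise SchemaError(
                    f"{node}: CPT shape {cpt.values.shape}, expected {expect}"
                )
        self._spec = by_name

    # -- vocabulary helpers -------------------------------------------------
    def spec(self, name: str) -> VariableSpec:
        return self._spec[name]

    def card(self, name: str) -> int:
        return len(self._spec[name].states)

    def state_index(self, name: str, state: str) -> int:
        try:
            return self._spec[name].states.index(state)
        except ValueError:
            raise SchemaError(f"{state!r} is not a state of {name}") from None

    def cpt_factor(self, node: str) -> Factor:
        cpt = self.cpts[node]
        return Factor(cpt.parents + (node,), cpt.values)

    def validate(self) -> None:
        for cpt in self.cpts.values():
            cpt.validate()


def joint_probability(
    network: BayesianNetwork, assignment: dict[str, str]
) -> float:
    """P(assignment) for a complete assignment: the CPT product."""
    missing = [n for n in network.structure.nodes if n not in assignment]
    if missing:
        raise SchemaError(f"assignment incomplete: missing {missing}")
    p = 1.0
    for node in network.structure.nodes:
        cpt = network.cpts[node]
        idx = tuple(
            network.state_index(par, assignment[par]) for par in cpt.parents
        ) + (network.state_index(node, assignment[node]),)
        p *= float(cpt.values[idx])
    return p


def _relevant_nodes(
    network: BayesianNetwork, query: set[str]
) -> set[str]:
    """Query nodes plus all their ancestors (barren descendants sum to 1)."""
    g = network.structure.graph()
    out = set(query)
    for q in query:
        out |= nx.ancestors(g, q)
    return out


def marginal(
    network: BayesianNetwork,
    evidence: dict[str, str],
    target: str,
) -> np.ndarray:
    """Exact posterior P(target | evidence) as a vector over the target's
    states (schema order).  Raises :class:`ImpossibleEvidenceError` when the
    evidence has zero probability under the model."""
    if target in evidence:
        raise SchemaError(f"target {target} is part of the evidence")
    ev_idx = {v: network.state_index(v, s) for v, s in evidence.items()}
    relevant = _relevant_nodes(network, set(ev_idx) | {target})
    const = 1.0
    factors: list[Factor] = []
    for node in relevant:
        f = network.cpt_factor(node).reduce(ev_idx)
        if not f.scope:
            const *= float(f.values)
        else:
            factors.append(f)
    elim = sorted({v for f in factors for v in f.scope} - {target})
    remaining = _eliminate(factors, elim)
    result = Factor((target,), np.ones(network.card(target)))
    for f in remaining:
        result = result.multiply(f)
    result = result.marginal_onto((target,))
    z = result.sum() * const
    if not (z > 0.0) or not math.isfinite(z):
        raise ImpossibleEvidenceError(
            f"evidence has zero probability (target {target})"
        )
    return result.values / result.values.sum()


def sample_codes(
    network: BayesianNetwork, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Ancestral sampling: (n, n_nodes) int array of state codes, columns in
    structure node order."""
    nodes = list(network.structure.nodes)
    col = {v: i for i, v in enumerate(nodes)}
    out = np.empty((n, len(nodes)), dtype=np.int16)
    for node in network.structure.topological_order():
        cpt = network.cpts[node]
        if cpt.parents:
            pidx = np.zeros(n, dtype=np.int64)
            dims = cpt.values.shape[:-1]
            pcols = np.stack(
                [out[:, col[p]].astype(np.int64) for p in cpt.parents]
            )
            pidx = np.ravel_multi_index(pcols, dims)
            rows = cpt.values.reshape(-1, cpt.values.shape[-1])[pidx]
        else:
            rows = np.broadcast_to(cpt.values, (n, cpt.values.shape[-1]))
        u = rng.random(n)
        cdf = np.cumsum(rows, axis=1)
        out[:, col[node]] = (u[:, None] < cdf).argmax(axis=1)
    return out


# ---------------------------------------------------------------------------
# EM parameter learning


@dataclass(frozen=True)
class LearnConfig:
    """EM settings: convergence on relative change of the penalized
    log-likelihood (default 1e-4), Laplace pseudocount fixed to the inverse
    of each node's parent-combination count."""

    convergence_threshold: float = 1e-4
    max_iterations: int = 200
    laplace_mode: str = "inverse-parent-combinations"
    seed: int = 0

    def __post_init__(self):
        if self.convergence_threshold <= 0:
            raise ValueError("convergence_threshold must be > 0")
        if self.laplace_mode != "inverse-parent-combinations":
            raise ValueError("only the 1/q Laplace mode is supported")


def _m_step(counts: dict[str, np.ndarray], alphas: dict[str, float]):
    thetas = {}
    for node, c in counts.items():
        a = alphas[node]
        r = c.shape[-1]
        thetas[node] = (c + a) / (c.sum(axis=-1, keepdims=True) + r * a)
    return thetas


def learn_em(
    structure: NetworkStructure,
    train: Cohort,
    config: LearnConfig = LearnConfig(),
    *,
    schema: list[VariableSpec] | None = None,
) -> BayesianNetwork:
    """Fit CPTs by EM with the 1/q Laplace prior.

    Complete rows contribute exact family counts; rows with missing values
    contribute expected counts from the exact posterior over their missing
    variables.  With no missingness this reduces to a single closed-form
    M-step: theta = (N + 1/q) / (N_parent + r/q).  Iteration stops when the
    relative change of the penalized observed-data log-likelihood falls
    below the convergence threshold.  Deterministic (the seed is accepted
    for interface symmetry; no randomized restarts are used).
    """
    schema = list(schema) if schema is not None else list(train.schema)
    by_name = {v.name: v for v in schema}
    nodes = list(structure.nodes)
    for node in nodes:
        if node not in by_name:
            raise SchemaError(f"no VariableSpec for node {node}")
    col = {v: i for i, v in enumerate(nodes)}
    cards = {v: len(by_name[v].states) for v in nodes}
    sidx = {v: {s: i for i, s in enumerate(by_name[v].states)} for v in nodes}
    parents = {v: structure.parents(v) for v in nodes}
    children = {v: structure.children(v) for v in nodes}
    family = {v: parents[v] + (v,) for v in nodes}
    q = {v: int(np.prod([cards[p] for p in parents[v]])) for v in nodes}
    alphas = {v: 1.0 / q[v] for v in nodes}

    extra = [
        v for v in train.variables if v not in col and v not in ("plan_id",)
    ]
    if extra:
        raise SchemaError(f"training variables not in structure: {extra}")

    n = len(train.plans)
    D = np.full((n, len(nodes)), -1, dtype=np.int16)
    for r, plan in enumerate(train.plans):
        for v, s in plan.assignments.items():
            if v in col:
                D[r, col[v]] = sidx[v][s]

    # --- complete-family counts and cached index arrays (theta-independent)
    base_counts: dict[str, np.ndarray] = {}
    flat_idx: dict[str, np.ndarray] = {}
    for v in nodes:
        fam_cols = [col[u] for u in family[v]]
        sub = D[:, fam_cols]
        mask = (sub >= 0).all(axis=1)
        dims = tuple(cards[u] for u in family[v])
        if mask.any():
            flat = np.ravel_multi_index(
                tuple(sub[mask, j].astype(np.int64) for j in range(len(fam_cols))),
                dims,
            )
            flat_idx[v] = flat
            base_counts[v] = np.bincount(
                flat, minlength=int(np.prod(dims))
            ).astype(float).reshape(dims)
        else:
            flat_idx[v] = np.empty(0, dtype=np.int64)
            base_counts[v] = np.zeros(dims, dtype=float)

    # --- group incomplete rows by (missing set, boundary evidence)
    groups: dict[tuple, int] = {}
    group_info: dict[tuple, tuple[tuple[str, ...], dict[str, int]]] = {}
    incomplete_rows = np.where((D < 0).any(axis=1))[0]
    for r in incomplete_rows:
        missing = tuple(v for v in nodes if D[r, col[v]] < 0)
        affected: set[str] = set()
        for m in missing:
            affected.add(m)
            affected.update(children[m])
        fam_vars: set[str] = set()
        for a in affected:
            fam_vars.update(family[a])
        boundary = tuple(sorted(fam_vars, key=col.__getitem__))
        key = (missing, tuple(int(D[r, col[u]]) for u in boundary))
        groups[key] = groups.get(key, 0) + 1
        if key not in group_info:
            ev = {
                u: int(D[r, col[u]])
                for u in boundary
                if D[r, col[u]] >= 0
            }
            group_info[key] = (
                tuple(sorted(affected, key=col.__getitem__)),
                ev,
            )

    def e_step(theta: dict[str, np.ndarray]):
        counts = {v: base_counts[v].copy() for v in nodes}
        ll = 0.0
        for v in nodes:
            if flat_idx[v].size:
                ll += float(
                    np.log(theta[v].reshape(-1)[flat_idx[v]]).sum()
                )
        for key, cnt in groups.items():
            missing, _ = key
            affected, ev = group_info[key]
            joint: Factor | None = None
            for a in affected:
                f = Factor(family[a], theta[a]).reduce(ev)
                joint = f if joint is None else joint.multiply(f)
            z = joint.sum()
            if not z > 0:
                raise ImpossibleEvidenceError(
                    "zero-probability record during EM"
                )
            ll += cnt * math.log(z)
            post = Factor(joint.scope, joint.values / z)
            for a in affected:
                fam = family[a]
                free = tuple(u for u in fam if u in missing)
                marg = post.marginal_onto(free)
                index: list = []
                shape: list[int] = []
                for u in fam:
                    if u in missing:
                        index.append(slice(None))
                        shape.append(cards[u])
                    else:
                        index.append(ev[u])
                counts[a][tuple(index)] += cnt * marg.values
        return counts, ll

    def penalty(theta: dict[str, np.ndarray]) -> float:
        return sum(
            alphas[v] * float(np.log(theta[v]).sum()) for v in nodes
        )

    theta = _m_step(base_counts, alphas)  # deterministic available-case init
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        counts, ll = e_step(theta)
        pll = ll + penalty(theta)
        trace.append(pll)
        theta = _m_step(counts, alphas)
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < config.convergence_threshold * abs(prev):
                converged = True
                break
        if not groups:
            # complete data: the M-step is closed-form and already final
            converged = True
            break

    cpts = {
        v: CPT(v, parents[v], theta[v]) for v in nodes
    }
    net = BayesianNetwork(
        NetworkStructure(tuple(nodes), tuple(structure.edges)),
        cpts,
        schema,
        learn_info={
            "iterations": it,
            "converged": converged,
            "penalized_loglik_trace": trace,
            "n_rows": n,
            "n_incomplete_rows": int(len(incomplete_rows)),
        },
    )
    return net


def effective_counts(
    network: BayesianNetwork, cohort: Cohort
) -> dict[str, np.ndarray]:
    """Observed complete-family counts per CPT row (diagnostic helper for
    judging which rows were actually informed by data)."""
    col = {v: i for i, v in enumerate(network.structure.nodes)}
    sidx = {
        v.name: {s: i for i, s in enumerate(v.states)} for v in network.schema
    }
    n = len(cohort.plans)
    D = np.full((n, len(col)), -1, dtype=np.int16)
    for r, plan in enumerate(cohort.plans):
        for v, s in plan.assignments.items():
            if v in col:
                D[r, col[v]] = sidx[v][s]
    out = {}
    for v in network.structure.nodes:
        fam = network.cpts[v].parents + (v,)
        sub = D[:, [col[u] for u in fam]]
        mask = (sub >= 0).all(axis=1)
        dims = tuple(network.card(u) for u in fam)
        if mask.any():
            flat = np.ravel_multi_index(
                tuple(sub[mask, j].astype(np.int64) for j in range(len(fam))),
                dims,
            )
            counts = np.bincount(flat, minlength=int(np.prod(dims)))
            out[v] = counts.reshape(dims).sum(axis=-1)
        else:
            out[v] = np.zeros(dims[:-1])
    return out


# ---------------------------------------------------------------------------
# Serialization: XMLBIF 0.3 plus a JSON sidecar for schema metadata


def _sidecar_path(path) -> str:
    return str(path) + ".meta.json"


def save_network(network: BayesianNetwork, path) -> None:
    """Write the network as XMLBIF 0.3; variable categories and clinic
    applicability (which XMLBIF cannot carry) go to a ``.meta.json``
    sidecar next to it."""
    bif = ET.Element("BIF", VERSION="0.3")
    netel = ET.SubElement(bif, "NETWORK")
    ET.SubElement(netel, "NAME").text = "rtplanqa"
    for spec in network.schema:
        var = ET.SubElement(netel, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = spec.name
        for s in spec.states:
            ET.SubElement(var, "OUTCOME").text = s
    for node in network.structure.nodes:
        cpt = network.cpts[node]
        d = ET.SubElement(netel, "DEFINITION")
        ET.SubElement(d, "FOR").text = node
        for p in cpt.parents:
            ET.SubElement(d, "GIVEN").text = p
        ET.SubElement(d, "TABLE").text = " ".join(
            repr(float(x)) for x in cpt.values.reshape(-1)
        )
    tree = ET.ElementTree(bif)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    meta = {
        "node_order": list(network.structure.nodes),
        "variables": {
            v.name: {
                "category": v.category,
                "applicable_clinics": (
                    "all"
                    if v.applicable_clinics == "all"
                    else sorted(v.applicable_clinics)
                ),
            }
            for v in network.schema
        },
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def load_network(path) -> BayesianNetwork:
    """Read an XMLBIF 0.3 file (and its sidecar when present).

    CPT rows that do not sum to one (beyond 1e-6) are rejected.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SchemaError(f"{path}: malformed XMLBIF ({exc})") from exc
    netel = tree.getroot().find("NETWORK")
    if netel is None:
        raise SchemaError(f"{path}: no NETWORK element")
    meta = None
    try:
        with open(_sidecar_path(path), encoding="utf-8") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    states: dict[str, tuple[str, ...]] = {}
    var_order: list[str] = []
    for var in netel.findall("VARIABLE"):
        name = var.findtext("NAME")
        outs = tuple(o.text for o in var.findall("OUTCOME"))
        if name is None or len(outs) < 2:
            raise SchemaError(f"{path}: variable with <2 outcomes")
        states[name] = outs
        var_order.append(name)
    edges: list[tuple[str, str]] = []
    cpts: dict[str, CPT] = {}
    for d in netel.findall("DEFINITION"):
        node = d.findtext("FOR")
        givens = tuple(g.text for g in d.findall("GIVEN"))
        if node not in states or any(g not in states for g in givens):
            raise SchemaError(f"{path}: DEFINITION references unknown variable")
        table = np.array(
            [float(x) for x in (d.findtext("TABLE") or "").split()]
        )
        shape = tuple(len(states[g]) for g in givens) + (len(states[node]),)
        if table.size != int(np.prod(shape)):
            raise SchemaError(
                f"{path}: {node} table has {table.size} entries, "
                f"expected {int(np.prod(shape))}"
            )
        cpt = CPT(node, givens, table.reshape(shape))
        cpt.validate()
        cpts[node] = cpt
        edges.extend((g, node) for g in givens)
    node_order = meta["node_order"] if meta else var_order
    structure = NetworkStructure(tuple(node_order), tuple(edges))
    schema = []
    for name in node_order:
        cat, clinics = "treatment_planning", "all"
        if meta and name in meta["variables"]:
            m = meta["variables"][name]
            cat = m["category"]
            clinics = (
                "all"
                if m["applicable_clinics"] == "all"
                else frozenset(m["applicable_clinics"])
            )
        if cat not in CATEGORIES:
            raise SchemaError(f"{path}: bad category {cat!r} for {name}")
        schema.append(VariableSpec(name, cat, states[name], clinics))
    # parents in sidecar/structure order may differ from GIVEN order; align
    fixed = {}
    for node, cpt in cpts.items():
        want = structure.parents(node)
        if want != cpt.parents:
            perm = [cpt.parents.index(p) for p in want] + [len(cpt.parents)]
            fixed[node] = CPT(node, want, np.transpose(cpt.values, perm))
        else:
            fixed[node] = cpt
    return BayesianNetwork(structure, fixed, schema)


def save_structure(structure: NetworkStructure, path) -> None:
    """Edge-list text format: one ``parent -> child`` per line; isolated
    nodes appear on their own line."""
    linked = {n for e in structure.edges for n in e}
    with open(path, "w", encoding="utf-8") as fh:
        for n in structure.nodes:
            if n not in linked:
                fh.write(f"{n}\n")
        for a, b in structure.edges:
            fh.write(f"{a} -> {b}\n")


def load_structure(path) -> NetworkStructure:
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" in line:
                a, _, b = line.partition("->")
                a, b = a.strip(), b.strip()
                if not a or not b:
                    raise SchemaError(f"{path}:{lineno}: bad edge line")
                for x in (a, b):
                    if x not in nodes:
                        nodes.append(x)
                edges.append((a, b))
            else:
                if line not in nodes:
                    nodes.append(line)
    return NetworkStructure(tuple(nodes), tuple(edges))
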