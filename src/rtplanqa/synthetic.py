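"""Multi-institutional synthetic plan cohorts.

Emulates the statistical structure of multi-clinic treatment-plan data:
every clinic shares one network structure, but clinic-specific practice
(different linac vendors, planning systems and protocols) is modelled by
perturbing the shared ground-truth CPT rows with a Dirichlet resample whose
concentration shrinks as the ``divergence`` knob grows.  Some variables are
structurally inapplicable at a clinic (sampled, then dropped), and
record-level missing-at-random missingness is applied per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ground_truth import base_network
from .network import CPT, BayesianNetwork, sample_codes
from .schema import Cohort, PlanRecord, VariableSpec

#: Dirichlet concentration scale; per-row concentration = KAPPA / divergence.
#: At divergence 1.0 this puts the mean total-variation distance between two
#: clinics' matching CPT rows near 0.2 (measure with :func:`cpt_divergence`).
KAPPA = 15.0

#: Default per-variable missing-at-random rates (unlisted variables: 0.02).
DEFAULT_MISSINGNESS = {
    "ssd": 0.08,
    "mu_per_degree": 0.06,
    "mu_per_cgy": 0.05,
    "t_stage": 0.05,
    "n_stage": 0.05,
    "m_stage": 0.05,
    "tolerance_table": 0.04,
}

#: Variables structurally absent per default clinic (clinic_c emulates an
#: institution whose planning system carries neither wedge nor tolerance
#: table fields).
DEFAULT_INAPPLICABLE = {
    "clinic_a": frozenset(),
    "clinic_b": frozenset(),
    "clinic_c": frozenset({"wedge", "tolerance_table"}),
}


@dataclass
class ClinicProfile:
    """One clinic's generative model."""

    clinic_id: str
    ground_truth: BayesianNetwork
    inapplicable_variables: frozenset[str] = frozenset()
    missingness: dict[str, float] = field(default_factory=dict)
    size_hint: int = 2000


@dataclass(frozen=True)
class GeneratorConfig:
    clinic_ids: tuple[str, ...] = ("clinic_a", "clinic_b", "clinic_c")
    n_per_clinic: int = 2000
    seed: int = 0
    divergence: float = 1.0

    def __post_init__(self):
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


def perturb_network(
    base: BayesianNetwork, divergence: float, rng: np.random.Generator
) -> BayesianNetwork:
    """Dirichlet-perturb every CPT row; divergence 0 returns the rows
    unchanged."""
    if divergence == 0:
        return base
    conc = KAPPA / divergence
    cpts = {}
    for node, cpt in base.cpts.items():
        flat = cpt.values.reshape(-1, cpt.values.shape[-1])
        out = np.empty_like(flat)
        for i, row in enumerate(flat):
            out[i] = rng.dirichlet(row * conc + 1e-3)
        cpts[node] = CPT(node, cpt.parents, out.reshape(cpt.values.shape))
    return BayesianNetwork(base.structure, cpts, base.schema)


def build_profiles(
    base: BayesianNetwork | None, config: GeneratorConfig
) -> list[ClinicProfile]:
    """One perturbed clinic profile per configured clinic id, seeded and
    reproducible."""
    if base is None:
        base = base_network()
    ss = np.random.SeedSequence(config.seed)
    profiles = []
    for clinic, child in zip(config.clinic_ids, ss.spawn(len(config.clinic_ids))):
        rng = np.random.default_rng(child)
        net = perturb_network(base, config.divergence, rng)
        profiles.append(
            ClinicProfile(
                clinic_id=clinic,
                ground_truth=net,
                inapplicable_variables=DEFAULT_INAPPLICABLE.get(
                    clinic, frozenset()
                ),
                missingness={
                    v.name: DEFAULT_MISSINGNESS.get(v.name, 0.02)
                    for v in base.schema
                },
                size_hint=config.n_per_clinic,
            )
        )
    return profiles


def cpt_divergence(a: BayesianNetwork, b: BayesianNetwork) -> float:
    """Mean total-variation distance between matching CPT rows."""
    tvs = []
    for node in a.structure.nodes:
        fa = a.cpts[node].values.reshape(-1, a.cpts[node].values.shape[-1])
        fb = b.cpts[node].values.reshape(-1, b.cpts[node].values.shape[-1])
        tvs.append(0.5 * np.abs(fa - fb).sum(axis=1))
    return float(np.concatenate(tvs).mean())


def sample_plans(profile: ClinicProfile, n: int, seed: int) -> Cohort:
    """Draw ``n`` plans by ancestral sampling from the clinic's ground
    truth, drop inapplicable variables, then apply missing-at-random
    masking per variable."""
    if n < 0:
        raise ValueError("n must be >= 0")
    net = profile.ground_truth
    nodes = list(net.structure.nodes)
    schema = [
        v if v.name not in profile.inapplicable_variables
        else VariableSpec(
            v.name, v.category, v.states,
            frozenset(),  # applicable nowhere as far as this clinic knows
        )
        for v in net.schema
    ]
    if n == 0:
        return Cohort([], schema)
    rng = np.random.default_rng(seed)
    codes = sample_codes(net, n, rng)
    keep = np.ones((n, len(nodes)), dtype=bool)
    for j, node in enumerate(nodes):
        if node in profile.inapplicable_variables:
            keep[:, j] = False
            continue
        rate = profile.missingness.get(node, 0.0)
        if rate > 0:
            keep[:, j] &= rng.random(n) >= rate
    states = {v.name: v.states for v in net.schema}
    plans = []
    for i in range(n):
        assignments = {
            node: states[node][codes[i, j]]
            for j, node in enumerate(nodes)
            if keep[i, j]
        }
        plans.append(
            PlanRecord(f"{profile.clinic_id}-{i:06d}", profile.clinic_id,
                       assignments)
        )
    return Cohort(plans, schema)


def describe_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-variable summary: missingness rate and state frequencies."""
    rows = []
    n = len(cohort)
    counts_by_clinic = {}
    for p in cohort.plans:
        counts_by_clinic[p.clinic] = counts_by_clinic.get(p.clinic, 0) + 1
    for spec in cohort.schema:
        freq: dict[str, int] = {}
        miss = 0
        for p in cohort.plans:
            s = p.assignments.get(spec.name)
            if s is None:
                miss += 1
            else:
                freq[s] = freq.get(s, 0) + 1
        rows.append(
            {
                "variable": spec.name,
                "category": spec.category,
                "n_states": len(spec.states),
                "missing_rate": miss / n if n else float("nan"),
                "top_state": max(freq, key=freq.get) if freq else "",
                "frequencies": {
                    s: c / n for s, c in sorted(freq.items())
                } if n else {},
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_plans"] = n
    df.attrs["per_clinic_counts"] = counts_by_clinic
    return df
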