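"""Conditional-probability scoring of plan variables and pass/alert/warning
tiers.

For each plan variable of interest the detector instantiates evidence (either
the diagnostic variables only, or every other observed variable), computes
the exact marginal probability of the observed state, and flags improbable
values.  Low probability means the observed value is rare given the rest of
the plan — the signature of a data-entry or planning error.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .defaults import DIAGNOSTIC_VARIABLES
from .network import BayesianNetwork, ImpossibleEvidenceError, marginal
from .schema import PlanRecord


@dataclass(frozen=True)
class EvidenceStrategy:
    """Which observed variables are instantiated as evidence.

    ``diagnostic_only`` mirrors the original intended use (stages, site and
    intent are assumed correct); ``all_but_target`` instantiates every other
    observed variable.
    """

    mode: str = "all_but_target"
    diagnostic_set: tuple[str, ...] = DIAGNOSTIC_VARIABLES

    def __post_init__(self):
        if self.mode not in ("diagnostic_only", "all_but_target"):
            raise ValueError(f"unknown strategy mode {self.mode!r}")

    def evidence_for(self, plan: PlanRecord, target: str) -> dict[str, str]:
        if self.mode == "diagnostic_only":
            pool = self.diagnostic_set
        else:
            pool = plan.assignments.keys()
        return {
            v: plan.assignments[v]
            for v in pool
            if v != target and v in plan.assignments
        }


@dataclass(frozen=True)
class DetectorConfig:
    """Two-threshold tiering: pass at or above the anomaly (alert)
    threshold, warning below the warning threshold, alert between."""

    anomaly_threshold: float = 0.05
    warning_threshold: float = 0.01
    strategy: EvidenceStrategy = field(default_factory=EvidenceStrategy)

    def __post_init__(self):
        if not (0 < self.warning_threshold < self.anomaly_threshold < 1):
            raise ValueError(
                "need 0 < warning_threshold < anomaly_threshold < 1"
            )


@dataclass(frozen=True)
class VariableScore:
    plan_id: str
    variable: str
    observed_state: str
    score: float
    tier: str
    evidence_used: tuple[tuple[str, str], ...]
    impossible_evidence: bool = False


def assign_tier(score: float, config: DetectorConfig) -> str:
    if score >= config.anomaly_threshold:
        return "pass"
    if score >= config.warning_threshold:
        return "alert"
    return "warning"


class PlanScorer:
    """Scores plans against a network, with two exact fast paths.

    Under the all-evidence strategy a target whose Markov blanket is fully
    observed is scored from its blanket factors alone; under the
    diagnostic-only strategy posteriors are cached per distinct evidence
    assignment, which collapses most of a cohort onto a few hundred exact
    inference calls.
    """

    def __init__(self, network: BayesianNetwork, config: DetectorConfig):
        self.network = network
        self.config = config
        self._cache: dict[tuple, np.ndarray] = {}
        self._children = {
            v: network.structure.children(v) for v in network.structure.nodes
        }

    def _posterior(self, evidence: dict[str, str], target: str) -> np.ndarray:
        key = (target, tuple(sorted(evidence.items())))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        post = marginal(self.network, evidence, target)
        self._cache[key] = post
        return post

    def _blanket_posterior(
        self, plan: PlanRecord, target: str
    ) -> np.ndarray | None:
        """Exact P(target | everything else) from the Markov blanket when the
        whole blanket is observed; None when it is not."""
        net = self.network
        cpt = net.cpts[target]
        try:
            pidx = tuple(
                net.state_index(p, plan.assignments[p]) for p in cpt.parents
            )
        except KeyError:
            return None
        logp = np.log(cpt.values[pidx])
        for child in self._children[target]:
            ccpt = net.cpts[child]
            if child not in plan.assignments:
                return None
            idx = []
            free_axis = None
            for ax, p in enumerate(ccpt.parents):
                if p == target:
                    idx.append(slice(None))
                    free_axis = ax
                elif p in plan.assignments:
                    idx.append(net.state_index(p, plan.assignments[p]))
                else:
                    return None
            idx.append(net.state_index(child, plan.assignments[child]))
            vals = ccpt.values[tuple(idx)]
            assert free_axis is not None
            logp = logp + np.log(vals)
        w = np.exp(logp - logp.max())
        return w / w.sum()

    def score_variable(
        self, plan: PlanRecord, target: str,
        strategy: EvidenceStrategy | None = None,
    ) -> VariableScore:
        strategy = strategy or self.config.strategy
        observed = plan.get(target)
        if observed is None:
            raise KeyError(f"{target} not assigned in plan {plan.plan_id}")
        evidence = strategy.evidence_for(plan, target)
        impossible = False
        post = None
        if strategy.mode == "all_but_target" and set(evidence) == (
            set(plan.assignments) - {target}
        ):
            post = self._blanket_posterior(plan, target)
        if post is None:
            try:
                post = self._posterior(evidence, target)
            except ImpossibleEvidenceError:
                impossible = True
        if impossible:
            score = sys.float_info.min
        else:
            score = float(post[self.network.state_index(target, observed)])
        return VariableScore(
            plan_id=plan.plan_id,
            variable=target,
            observed_state=observed,
            score=score,
            tier=assign_tier(score, self.config),
            evidence_used=tuple(sorted(evidence.items())),
            impossible_evidence=impossible,
        )

    def score_plan(self, plan: PlanRecord) -> list[VariableScore]:
        """One score per assigned non-diagnostic variable; diagnostic
        variables are assumed correct and never scored."""
        out = []
        for node in self.network.structure.nodes:
            if node in self.config.strategy.diagnostic_set:
                continue
            if node not in plan.assignments:
                continue
            out.append(self.score_variable(plan, node))
        return out


def score_variable(
    network: BayesianNetwork,
    plan: PlanRecord,
    target: str,
    strategy: EvidenceStrategy,
) -> VariableScore:
    cfg = DetectorConfig(strategy=strategy)
    return PlanScorer(network, cfg).score_variable(plan, target)


def score_plan(
    network: BayesianNetwork, plan: PlanRecord, config: DetectorConfig
) -> list[VariableScore]:
    return PlanScorer(network, config).score_plan(plan)


def scores_to_frame(scores: list[VariableScore]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "plan_id": s.plan_id,
                "variable": s.variable,
                "state": s.observed_state,
                "score": s.score,
                "tier": s.tier,
            }
            for s in scores
        ],
        columns=["plan_id", "variable", "state", "score", "tier"],
    )
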