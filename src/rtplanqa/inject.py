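"""Simulated-error embedding for test cohorts.

Mirrors the high-risk failure modes a physics plan review is meant to catch:
a configurable fraction of test plans (default 5%) receives simulated errors
drawn from three categories — patient setup (a table angle off by 10
degrees, a bolus wrongly present or absent, a flipped orientation),
treatment planning (gantry or collimator rotated by 20-30 degrees,
implausibly extreme plan-complexity surrogates, swapped beam parameters) and
dose prescription (three fractionation-scheme corruption schemes).  Every
injected value is a legal state of the binned vocabulary, so erroneous plans
are indistinguishable from clean ones except statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .defaults import (
    interval_bin,
    interval_representative,
    nfx_bin,
    nfx_representative,
    parse_interval,
)
from .schema import Cohort, PlanRecord

CATEGORIES = ("setup", "planning", "prescription")


class IncompatibleError(ValueError):
    """The chosen error cannot be realized on this plan (e.g. the variable
    has no alternative state)."""


@dataclass(frozen=True)
class ErrorSpec:
    """One injectable failure mode: a target variable and a named transform."""

    category: str
    variable: str
    transform: str


@dataclass(frozen=True)
class InjectionRecord:
    """Ground truth for one injected (plan, variable) corruption."""

    plan_id: str
    variable: str
    original_state: str
    injected_state: str
    category: str
    approach: int | None = None


@dataclass(frozen=True)
class InjectionConfig:
    rate: float = 0.05
    category_weights: dict = field(
        default_factory=lambda: {"setup": 1.0, "planning": 1.0,
                                 "prescription": 1.0}
    )
    errors_per_plan: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rate <= 1):
            raise ValueError("rate must be in [0, 1]")
        w = self.category_weights
        if any(x < 0 for x in w.values()) or sum(w.values()) <= 0:
            raise ValueError("category weights must be >= 0, not all zero")


def default_error_specs() -> list[ErrorSpec]:
    E = ErrorSpec
    return [
        E("setup", "table_angle", "shift-angle-bin"),
        E("setup", "bolus", "toggle"),
        E("setup", "patient_orientation", "swap"),
        E("setup", "tolerance_table", "swap"),
        E("planning", "gantry_angle", "shift-angle-20-30"),
        E("planning", "collimator_angle", "shift-angle-20-30"),
        E("planning", "mu_per_cgy", "extreme-bin"),
        E("planning", "mu_per_degree", "extreme-bin"),
        E("planning", "beam_energy", "swap"),
        E("planning", "radiation_type", "swap"),
        E("planning", "number_of_beams", "swap"),
        E("planning", "ssd", "swap"),
        E("planning", "wedge", "swap"),
        E("prescription", "prescription", "prescription-approach-1"),
        E("prescription", "prescription", "prescription-approach-2"),
        E("prescription", "prescription", "prescription-approach-3"),
    ]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _swap(states, current: str, rng) -> str:
    others = [s for s in states if s != current]
    if not others:
        raise IncompatibleError("no alternative state")
    return others[int(rng.integers(len(others)))]


def _angle_shift(states, current: str, rng, lo: float, hi: float) -> str:
    """Shift the bin by a raw-angle offset drawn in [lo, hi] degrees, sign
    random, wrapping at 360."""
    i = states.index(current)
    width = 360.0 / len(states)
    center = i * width + width / 2.0
    offset = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
    j = int(((center + offset) % 360.0) // width)
    if j == i:  # guaranteed not to happen for offsets >= one bin width
        raise IncompatibleError("offset did not cross a bin boundary")
    return states[j]


def setup_error(
    plan: PlanRecord, spec: ErrorSpec, seed, cohort: Cohort
) -> tuple[PlanRecord, InjectionRecord]:
    """Patient-setup corruption: the table angle moves exactly one 10-degree
    bin (direction random, wraparound), bolus toggles, orientation and
    tolerance table swap to a different state."""
    if spec.category != "setup":
        raise ValueError("not a setup spec")
    rng = _as_rng(seed)
    current = plan.get(spec.variable)
    if current is None:
        raise IncompatibleError(f"{spec.variable} not assigned")
    states = list(cohort.spec(spec.variable).states)
    if spec.transform == "shift-angle-bin":
        i = states.index(current)
        step = 1 if rng.random() < 0.5 else -1
        new = states[(i + step) % len(states)]
    elif spec.transform == "toggle":
        new = _swap(states, current, rng)
    elif spec.transform == "swap":
        new = _swap(states, current, rng)
    else:
        raise ValueError(f"unknown setup transform {spec.transform!r}")
    rec = InjectionRecord(plan.plan_id, spec.variable, current, new, "setup")
    return plan.with_assignment(spec.variable, new), rec


def planning_error(
    plan: PlanRecord, spec: ErrorSpec, seed, cohort: Cohort
) -> tuple[PlanRecord, InjectionRecord]:
    """Treatment-planning corruption: gantry/collimator shifted by a uniform
    20-30 degree offset and re-binned, complexity surrogates forced to an
    extreme bin, other beam parameters swapped."""
    if spec.category != "planning":
        raise ValueError("not a planning spec")
    rng = _as_rng(seed)
    current = plan.get(spec.variable)
    if current is None:
        raise IncompatibleError(f"{spec.variable} not assigned")
    states = list(cohort.spec(spec.variable).states)
    if spec.transform == "shift-angle-20-30":
        new = _angle_shift(states, current, rng, 20.0, 30.0)
    elif spec.transform == "extreme-bin":
        extremes = [s for s in (states[0], states[-1]) if s != current]
        if not extremes:
            raise IncompatibleError("no differing extreme bin")
        new = extremes[int(rng.integers(len(extremes)))]
    elif spec.transform == "swap":
        new = _swap(states, current, rng)
    else:
        raise ValueError(f"unknown planning transform {spec.transform!r}")
    rec = InjectionRecord(plan.plan_id, spec.variable, current, new, "planning")
    return plan.with_assignment(spec.variable, new), rec


_PRESCRIPTION_VARS = ("ptv_dose", "number_of_fractions", "dose_per_fraction")


def prescription_error(
    plan: PlanRecord, approach: int, seed, cohort: Cohort
) -> tuple[PlanRecord, list[InjectionRecord]]:
    """Fractionation-scheme corruption, three schemes:

    1. dose-per-fraction and fraction count change jointly so the total
       (PTV) dose stays in its original bin;
    2. PTV dose and fraction count change, dose-per-fraction held;
    3. PTV dose and dose-per-fraction change, fraction count held.

    At least one altered variable lands in a different bin.  Returns one
    record per variable whose binned state actually changed.
    """
    if approach not in (1, 2, 3):
        raise ValueError("approach must be 1, 2 or 3")
    rng = _as_rng(seed)
    vals = {v: plan.get(v) for v in _PRESCRIPTION_VARS}
    if any(v is None for v in vals.values()):
        raise IncompatibleError("prescription variables not all assigned")
    ptv_states = cohort.spec("ptv_dose").states
    nfx_states = cohort.spec("number_of_fractions").states
    dpf_states = cohort.spec("dose_per_fraction").states
    ptv0, nfx0, dpf0 = (
        vals["ptv_dose"], vals["number_of_fractions"], vals["dose_per_fraction"]
    )
    new = dict(vals)
    if approach == 1:
        ptv_ref = interval_representative(ptv0, 400.0)
        lo, hi = parse_interval(ptv0)
        cands = []
        for n in range(1, 61):
            d = ptv_ref / n
            if not (lo <= n * d < hi):
                continue
            try:
                nfx_new = nfx_bin(n, nfx_states)
                dpf_new = interval_bin(min(d, 599.0), dpf_states)
            except ValueError:
                continue
            if nfx_new != nfx0 or dpf_new != dpf0:
                cands.append((nfx_new, dpf_new))
        cands = sorted(set(cands))
        if not cands:
            raise IncompatibleError("no alternative isodose scheme")
        nfx_new, dpf_new = cands[int(rng.integers(len(cands)))]
        new["number_of_fractions"], new["dose_per_fraction"] = nfx_new, dpf_new
    elif approach == 2:
        dpf_ref = interval_representative(dpf0, 100.0)
        cands = []
        for n in range(1, 61):
            nfx_new = nfx_bin(n, nfx_states)
            if nfx_new == nfx0:
                continue
            try:
                ptv_new = interval_bin(dpf_ref * n, ptv_states)
            except ValueError:
                continue
            cands.append((nfx_new, ptv_new))
        cands = sorted(set(cands))
        if not cands:
            raise IncompatibleError("no alternative scheme with fixed dose/fx")
        nfx_new, ptv_new = cands[int(rng.integers(len(cands)))]
        new["number_of_fractions"], new["ptv_dose"] = nfx_new, ptv_new
    else:
        n_ref = nfx_representative(nfx0)
        cands = []
        for dpf_new in dpf_states:
            if dpf_new == dpf0:
                continue
            d = interval_representative(dpf_new, 100.0)
            try:
                ptv_new = interval_bin(d * n_ref, ptv_states)
            except ValueError:
                continue
            cands.append((dpf_new, ptv_new))
        if not cands:
            raise IncompatibleError("no alternative scheme with fixed fractions")
        dpf_new, ptv_new = cands[int(rng.integers(len(cands)))]
        new["dose_per_fraction"], new["ptv_dose"] = dpf_new, ptv_new
    records = []
    out = plan
    for v in _PRESCRIPTION_VARS:
        if new[v] != vals[v]:
            out = out.with_assignment(v, new[v])
            records.append(
                InjectionRecord(plan.plan_id, v, vals[v], new[v],
                                "prescription", approach)
            )
    if not records:
        raise IncompatibleError("prescription transform changed nothing")
    return out, records


def _apply_spec(
    plan: PlanRecord, spec: ErrorSpec, rng, cohort: Cohort
) -> tuple[PlanRecord, list[InjectionRecord]]:
    if spec.category == "setup":
        p, r = setup_error(plan, spec, rng, cohort)
        return p, [r]
    if spec.category == "planning":
        p, r = planning_error(plan, spec, rng, cohort)
        return p, [r]
    approach = int(spec.transform.rsplit("-", 1)[1])
    return prescription_error(plan, approach, rng, cohort)


def inject_errors(
    test: Cohort,
    specs: list[ErrorSpec] | None = None,
    config: InjectionConfig = InjectionConfig(),
) -> tuple[Cohort, list[InjectionRecord]]:
    """Corrupt exactly ``round(rate * n)`` plans of the test cohort.

    Per corrupted plan, ``errors_per_plan`` error events are embedded: the
    category is drawn from ``category_weights``, then a compatible failure
    mode uniformly within it.  Plans on which no configured failure mode is
    realizable are skipped and replaced by a redraw (logged in the returned
    cohort's ``injection_log``).  Unmodified plans are returned unchanged.
    """
    if specs is None:
        specs = default_error_specs()
    rng = np.random.default_rng(config.seed)
    n = len(test)
    n_mod = int(round(config.rate * n))
    order = rng.permutation(n)
    plans = list(test.plans)
    records: list[InjectionRecord] = []
    log: list[str] = []
    modified = 0
    cursor = 0
    cats = [c for c in CATEGORIES if config.category_weights.get(c, 0) > 0]
    weights = np.array([config.category_weights[c] for c in cats], dtype=float)
    weights /= weights.sum()
    while modified < n_mod and cursor < n:
        i = int(order[cursor])
        cursor += 1
        plan = plans[i]
        plan_records: list[InjectionRecord] = []
        ok = True
        for _ in range(config.errors_per_plan):
            done = False
            remaining_cats = list(cats)
            cat_weights = weights.copy()
            while remaining_cats and not done:
                k = int(rng.choice(len(remaining_cats),
                                   p=cat_weights / cat_weights.sum()))
                cat = remaining_cats.pop(k)
                cat_weights = np.delete(cat_weights, k)
                pool = [s for s in specs if s.category == cat]
                while pool and not done:
                    j = int(rng.integers(len(pool)))
                    spec = pool.pop(j)
                    try:
                        plan, recs = _apply_spec(plan, spec, rng, test)
                    except IncompatibleError as exc:
                        log.append(
                            f"{plan.plan_id}: {spec.variable}/{spec.transform}"
                            f" incompatible ({exc})"
                        )
                        continue
                    plan_records.extend(recs)
                    done = True
            if not done:
                log.append(f"{plan.plan_id}: no compatible failure mode; redrawn")
                ok = False
                break
        if not ok:
            continue
        plans[i] = plan
        records.extend(plan_records)
        modified += 1
    if modified < n_mod:
        log.append(
            f"only {modified}/{n_mod} plans could be corrupted"
        )
    out = Cohort(plans, test.schema)
    out.injection_log = log
    return out, records


def records_to_frame(records: list[InjectionRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "plan_id": r.plan_id,
                "variable": r.variable,
                "original": r.original_state,
                "injected": r.injected_state,
                "category": r.category,
                "approach": r.approach if r.approach is not None else "",
            }
            for r in records
        ],
        columns=["plan_id", "variable", "original", "injected", "category",
                 "approach"],
    )
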