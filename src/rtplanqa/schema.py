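"""Plan data model: variables, discrete states, binning, cohorts and splits.

A treatment plan is a (possibly partial) assignment of discrete states to a
fixed vocabulary of plan variables.  Variables fall into four categories —
diagnostic, patient setup, treatment planning and dose prescription — and
continuous quantities (angles, doses, monitor-unit ratios) are discretized
into named bins before any probabilistic modelling.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

CATEGORIES = (
    "diagnostic",
    "patient_setup",
    "treatment_planning",
    "dose_prescription",
)

#: Reserved state label for raw values outside a binning rule's declared domain.
OUT_OF_RANGE = "<out-of-range>"


class SchemaError(ValueError):
    """Raised for malformed variable specs, binning rules or plan tables."""


@dataclass(frozen=True)
class VariableSpec:
    """One discrete plan variable: its category and ordered state vocabulary.

    ``applicable_clinics`` is ``"all"`` or a frozenset of clinic identifiers;
    at clinics outside that set the variable is structurally missing (it does
    not exist in that clinic's practice, e.g. a wedge field at a clinic whose
    linacs have no wedges) and must never be assigned.
    """

    name: str
    category: str
    states: tuple[str, ...]
    applicable_clinics: frozenset[str] | str = "all"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"{self.name}: unknown category {self.category!r}"
            )
        if len(self.states) < 2:
            raise SchemaError(f"{self.name}: needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise SchemaError(f"{self.name}: duplicate state labels")

    def applicable_at(self, clinic: str) -> bool:
        if self.applicable_clinics == "all":
            return True
        return clinic in self.applicable_clinics


@dataclass(frozen=True)
class BinningRule:
    """Maps raw values to state labels.

    ``categorical_passthrough``: the raw value must already be one of the
    labels.  ``numeric_interval``: half-open, lower-inclusive intervals
    ``[b[i], b[i+1])``; a final boundary of ``inf`` makes an open top bin.
    Units are the field's conventional ones: degrees for angles, cGy for
    doses, MU-derived ratios for the complexity surrogates.
    """

    variable: str
    kind: str
    labels: tuple[str, ...]
    boundaries: tuple[float, ...] = ()

    def __post_init__(self):
        if self.kind not in ("categorical_passthrough", "numeric_interval"):
            raise SchemaError(f"{self.variable}: unknown kind {self.kind!r}")
        if self.kind == "numeric_interval":
            b = self.boundaries
            if len(b) < 2 or any(x >= y for x, y in zip(b, b[1:])):
                raise SchemaError(
                    f"{self.variable}: boundaries must be strictly increasing"
                )
            if len(self.labels) != len(b) - 1:
                raise SchemaError(
                    f"{self.variable}: {len(self.labels)} labels for "
                    f"{len(b) - 1} intervals"
                )


def bin_value(raw, rule: BinningRule) -> str:
    """Deterministically map one raw value to a state label.

    Values outside the declared domain map to the reserved
    :data:`OUT_OF_RANGE` label rather than silently to missing.
    """
    if rule.kind == "categorical_passthrough":
        s = str(raw)
        return s if s in rule.labels else OUT_OF_RANGE
    x = float(raw)
    b = rule.boundaries
    if x < b[0] or x >= b[-1]:
        return OUT_OF_RANGE
    # half-open, lower-inclusive: [b[i], b[i+1])
    i = int(np.searchsorted(b, x, side="right")) - 1
    return rule.labels[i]


@dataclass(frozen=True)
class PlanRecord:
    """One treatment plan: a partial assignment of states to variables."""

    plan_id: str
    clinic: str
    assignments: dict[str, str] = field(default_factory=dict)

    def get(self, variable: str) -> str | None:
        return self.assignments.get(variable)

    def with_assignment(self, variable: str, state: str) -> "PlanRecord":
        new = dict(self.assignments)
        new[variable] = state
        return replace(self, assignments=new)


@dataclass
class Cohort:
    """A set of plans sharing a variable schema."""

    plans: list[PlanRecord]
    schema: list[VariableSpec]

    def __post_init__(self):
        ids = [p.plan_id for p in self.plans]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate plan_ids in cohort")

    def __len__(self) -> int:
        return len(self.plans)

    def __iter__(self):
        return iter(self.plans)

    @property
    def variables(self) -> list[str]:
        return [v.name for v in self.schema]

    def spec(self, name: str) -> VariableSpec:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def clinics(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.plans:
            seen.setdefault(p.clinic, None)
        return list(seen)

    def filter_clinic(self, clinic: str) -> "Cohort":
        return Cohort([p for p in self.plans if p.clinic == clinic], self.schema)

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in self.plans:
            row = {"plan_id": p.plan_id, "clinic": p.clinic}
            for v in self.schema:
                row[v.name] = p.assignments.get(v.name, "")
            rows.append(row)
        cols = ["plan_id", "clinic"] + self.variables
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class SplitConfig:
    """Train/test split: default 80% training, clinic-stratified."""

    train_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction <= 1):
            raise SchemaError("train_fraction must be in (0, 1]")


@dataclass
class LoadReport:
    """Counts of coercions applied while reading a plan table."""

    n_plans: int = 0
    n_cells: int = 0
    n_missing: int = 0
    coerced_cells: int = 0
    dropped_inapplicable: int = 0
    ignored_columns: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def load_plans(
    path,
    schema: list[VariableSpec],
    *,
    clinic: str | None = None,
    strict_columns: bool = False,
) -> tuple[Cohort, LoadReport]:
    """Read a plan table (UTF-8 CSV, header row, empty string = missing).

    Cells whose value is not in the variable's state vocabulary become
    missing and are counted as coercions in the returned :class:`LoadReport`.
    Values assigned to a variable not applicable at the record's clinic are
    dropped to structural missing.  A ``clinic`` column is expected unless
    ``clinic`` is given.
    """
    by_name = {v.name: v for v in schema}
    report = LoadReport()
    plans: list[PlanRecord] = []
    seen_ids: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        if "plan_id" not in reader.fieldnames:
            raise SchemaError(f"{path}: missing plan_id column")
        unknown = [
            c
            for c in reader.fieldnames
            if c not in by_name and c not in ("plan_id", "clinic")
        ]
        if unknown and strict_columns:
            raise SchemaError(f"{path}: unknown columns {unknown}")
        report.ignored_columns = unknown
        for row in reader:
            pid = (row.get("plan_id") or "").strip()
            if not pid:
                raise SchemaError(f"{path}: row with empty plan_id")
            if pid in seen_ids:
                raise SchemaError(f"{path}: duplicate plan_id {pid!r}")
            seen_ids.add(pid)
            cl = clinic if clinic is not None else (row.get("clinic") or "").strip()
            assignments: dict[str, str] = {}
            for name, spec in by_name.items():
                raw = (row.get(name) or "").strip()
                report.n_cells += 1
                if not raw:
                    report.n_missing += 1
                    continue
                if not spec.applicable_at(cl):
                    report.dropped_inapplicable += 1
                    continue
                if raw not in spec.states:
                    report.coerced_cells += 1
                    report.n_missing += 1
                    continue
                assignments[name] = raw
            plans.append(PlanRecord(pid, cl, assignments))
    if not plans:
        raise SchemaError(f"{path}: no plan rows")
    report.n_plans = len(plans)
    return Cohort(plans, list(schema)), report


def save_plans(cohort: Cohort, path) -> None:
    """Write a cohort back to the CSV contract of :func:`load_plans`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plan_id", "clinic"] + cohort.variables)
        for p in cohort.plans:
            writer.writerow(
                [p.plan_id, p.clinic]
                + [p.assignments.get(v, "") for v in cohort.variables]
            )


def _allocate(counts: list[int], fraction: float, total_target: int) -> list[int]:
    """Largest-remainder allocation of per-stratum train counts summing to
    ``total_target``."""
    raw = [c * fraction for c in counts]
    base = [int(np.floor(r)) for r in raw]
    short = total_target - sum(base)
    order = sorted(
        range(len(counts)), key=lambda i: (raw[i] - base[i]), reverse=True
    )
    for i in order:
        if short <= 0:
            break
        if base[i] < counts[i]:
            base[i] += 1
            short -= 1
    # If still short (flooring left no headroom), top up anywhere possible.
    i = 0
    while short > 0 and i < len(base):
        room = counts[i] - base[i]
        take = min(room, short)
        base[i] += take
        short -= take
        i += 1
    return base


def split_cohort(cohort: Cohort, config: SplitConfig) -> tuple[Cohort, Cohort]:
    """Disjoint train/test partition, stratified by clinic.

    The training partition holds ``round(train_fraction * n)`` plans exactly;
    per-clinic counts are assigned by largest remainder so strata stay
    proportionally represented.  Reproducible for a fixed seed.
    """
    n = len(cohort)
    if n == 0:
        raise SchemaError("cannot split an empty cohort")
    target = int(round(config.train_fraction * n))
    clinics = cohort.clinics
    per_clinic = [[p for p in cohort.plans if p.clinic == c] for c in clinics]
    alloc = _allocate([len(g) for g in per_clinic], config.train_fraction, target)
    rng = np.random.default_rng(config.seed)
    train: list[PlanRecord] = []
    test: list[PlanRecord] = []
    for group, k in zip(per_clinic, alloc):
        idx = rng.permutation(len(group))
        train.extend(group[i] for i in idx[:k])
        test.extend(group[i] for i in idx[k:])
    return Cohort(train, cohort.schema), Cohort(test, cohort.schema)


def merge_cohorts(cohorts: list[Cohort]) -> Cohort:
    """Union of cohorts: schema states are unioned per variable, plan ids are
    namespaced by clinic when they would otherwise collide."""
    if not cohorts:
        raise SchemaError("nothing to merge")
    # Union schema, preserving first-seen variable and state order.
    merged: dict[str, VariableSpec] = {}
    for coh in cohorts:
        for spec in coh.schema:
            if spec.name not in merged:
                merged[spec.name] = spec
                continue
            prev = merged[spec.name]
            if prev.category != spec.category:
                raise SchemaError(
                    f"{spec.name}: conflicting categories "
                    f"{prev.category!r} vs {spec.category!r}"
                )
            extra = tuple(s for s in spec.states if s not in prev.states)
            if extra:
                merged[spec.name] = replace(prev, states=prev.states + extra)
            if prev.applicable_clinics != "all" and spec.applicable_clinics != "all":
                merged[spec.name] = replace(
                    merged[spec.name],
                    applicable_clinics=frozenset(prev.applicable_clinics)
                    | frozenset(spec.applicable_clinics),
                )
            elif spec.applicable_clinics == "all":
                merged[spec.name] = replace(
                    merged[spec.name], applicable_clinics="all"
                )
    ids_seen: set[str] = set()
    duplicated = False
    for coh in cohorts:
        for p in coh.plans:
            if p.plan_id in ids_seen:
                duplicated = True
            ids_seen.add(p.plan_id)
    plans: list[PlanRecord] = []
    for coh in cohorts:
        for p in coh.plans:
            pid = f"{p.clinic}:{p.plan_id}" if duplicated else p.plan_id
            plans.append(replace(p, plan_id=pid))
    return Cohort(plans, list(merged.values()))


# ---------------------------------------------------------------------------
# YAML round-trip for schema + binning configuration


def schema_to_yaml(schema: list[VariableSpec], rules: list[BinningRule], path):
    doc = {
        "variables": [
            {
                "name": v.name,
                "category": v.category,
                "states": list(v.states),
                "applicable_clinics": (
                    "all"
                    if v.applicable_clinics == "all"
                    else sorted(v.applicable_clinics)
                ),
            }
            for v in schema
        ],
        "binning": [
            {
                "variable": r.variable,
                "kind": r.kind,
                "labels": list(r.labels),
                "boundaries": list(r.boundaries),
            }
            for r in rules
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def schema_from_yaml(path) -> tuple[list[VariableSpec], list[BinningRule]]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    schema = [
        VariableSpec(
            d["name"],
            d["category"],
            tuple(d["states"]),
            "all"
            if d.get("applicable_clinics", "all") == "all"
            else frozenset(d["applicable_clinics"]),
        )
        for d in doc["variables"]
    ]
    rules = [
        BinningRule(
            d["variable"],
            d["kind"],
            tuple(d["labels"]),
            tuple(d.get("boundaries", ())),
        )
        for d in doc.get("binning", [])
    ]
    return schema, rules
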