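"""Default variable vocabulary, binning table and network structure.

The shipped network covers 24 plan variables: 5 diagnostic (TNM stages,
anatomic tumor location, treatment intent), 5 patient-setup, 11
treatment-planning and 3 dose-prescription variables, connected by 41
directed edges authored from clinical dependency reasoning (intent drives
fractionation, technique drives beam geometry and plan complexity, and so
on).  All vocabularies and bins are overridable through the YAML schema
format; these defaults keep bin widths coarse enough to be learnable from a
few thousand plans yet fine enough that the canonical simulated error
magnitudes (a 10 degree table-angle offset, a 20-30 degree gantry offset)
always cross a bin boundary.
"""

from __future__ import annotations

from .schema import BinningRule, VariableSpec

# --- interval-label arithmetic ---------------------------------------------


def parse_interval(label: str) -> tuple[float, float]:
    """Parse a "[lo,hi)" state label; ``hi`` may be ``inf``."""
    body = label.strip("[)")
    lo, hi = body.split(",")
    return float(lo), float(hi)


def interval_representative(label: str, open_top_margin: float = 100.0) -> float:
    """Representative raw value of an interval bin (midpoint; open top bins
    use lower bound plus ``open_top_margin``)."""
    lo, hi = parse_interval(label)
    if hi == float("inf"):
        return lo + open_top_margin
    return (lo + hi) / 2.0


def nfx_representative(label: str) -> int:
    """Midpoint integer of a fraction-count bin like "16-20" or ">40"."""
    if label.startswith(">"):
        return int(label[1:]) + 2
    lo, hi = label.split("-")
    return (int(lo) + int(hi)) // 2


def nfx_bin(n: int, labels) -> str:
    for lab in labels:
        if lab.startswith(">"):
            if n > int(lab[1:]):
                return lab
        else:
            lo, hi = lab.split("-")
            if int(lo) <= n <= int(hi):
                return lab
    raise ValueError(f"no fraction bin for {n}")


def interval_bin(x: float, labels) -> str:
    for lab in labels:
        lo, hi = parse_interval(lab)
        if lo <= x < hi:
            return lab
    raise ValueError(f"no interval bin for {x}")


DIAGNOSTIC_VARIABLES = (
    "t_stage",
    "n_stage",
    "m_stage",
    "tumor_site",
    "treatment_intent",
)


def angle_labels(width: int = 10) -> tuple[str, ...]:
    return tuple(f"[{lo},{lo + width})" for lo in range(0, 360, width))


def interval_labels(boundaries) -> tuple[str, ...]:
    out = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        hi_s = "inf" if hi == float("inf") else f"{hi:g}"
        out.append(f"[{lo:g},{hi_s})")
    return tuple(out)


ANGLE_STATES = angle_labels()

_DPF_BOUNDS = tuple(float(x) for x in range(0, 501, 50)) + (float("inf"),)
DPF_STATES = interval_labels(_DPF_BOUNDS)

_PTV_BOUNDS = tuple(float(x) for x in range(0, 8001, 500)) + (float("inf"),)
PTV_STATES = interval_labels(_PTV_BOUNDS)

NFX_STATES = (
    "1-5", "6-10", "11-15", "16-20", "21-25",
    "26-30", "31-35", "36-40", ">40",
)
_NFX_BOUNDS = (1.0, 6.0, 11.0, 16.0, 21.0, 26.0, 31.0, 36.0, 41.0, float("inf"))

_MU_CGY_BOUNDS = (0.0, 1.5, 2.5, 3.5, 5.0, float("inf"))
MU_CGY_STATES = interval_labels(_MU_CGY_BOUNDS)

_MU_DEG_BOUNDS = (0.0, 2.0, 4.0, 8.0, 16.0, float("inf"))
MU_DEG_STATES = interval_labels(_MU_DEG_BOUNDS)

_SSD_BOUNDS = (60.0, 70.0, 80.0, 90.0, 100.0, 110.0)
SSD_STATES = interval_labels(_SSD_BOUNDS)


def default_schema() -> list[VariableSpec]:
    V = VariableSpec
    return [
        # Diagnostic evidence
        V("tumor_site", "diagnostic",
          ("breast", "lung", "prostate", "head_neck", "rectum", "brain",
           "bone_met")),
        V("t_stage", "diagnostic", ("T0", "T1", "T2", "T3", "T4", "Tx")),
        V("n_stage", "diagnostic", ("N0", "N1", "N2", "N3", "Nx")),
        V("m_stage", "diagnostic", ("M0", "M1", "Mx")),
        V("treatment_intent", "diagnostic", ("curative", "palliative")),
        # Patient setup
        V("bolus", "patient_setup", ("no", "yes")),
        V("patient_orientation", "patient_setup",
          ("head_first_supine", "head_first_prone", "feet_first_supine")),
        V("table_angle", "patient_setup", ANGLE_STATES),
        V("tolerance_table", "patient_setup",
          ("standard", "sbrt", "electron", "clinical")),
        V("image_guidance", "patient_setup",
          ("daily_cbct", "daily_kv", "weekly_port", "none")),
        # Treatment planning
        V("treatment_technique", "treatment_planning",
          ("3dcrt", "imrt", "vmat", "electron")),
        V("radiation_type", "treatment_planning", ("photon", "electron")),
        V("beam_energy", "treatment_planning",
          ("6MV", "10MV", "15MV", "6FFF", "9MeV", "12MeV")),
        V("number_of_beams", "treatment_planning",
          ("1", "2", "3", "4", "5-7", "8+")),
        V("ssd", "treatment_planning", SSD_STATES),
        V("collimator_angle", "treatment_planning", ANGLE_STATES),
        V("gantry_angle", "treatment_planning", ANGLE_STATES),
        V("wedge", "treatment_planning", ("none", "physical", "dynamic")),
        V("mu_per_cgy", "treatment_planning", MU_CGY_STATES),
        V("mu_per_degree", "treatment_planning", MU_DEG_STATES),
        V("dose_rate", "treatment_planning", ("low", "standard", "high")),
        # Dose prescription
        V("ptv_dose", "dose_prescription", PTV_STATES),
        V("number_of_fractions", "dose_prescription", NFX_STATES),
        V("dose_per_fraction", "dose_prescription", DPF_STATES),
    ]


def default_binning() -> list[BinningRule]:
    """Binning table for raw plan values (degrees, cGy, MU ratios, cm)."""
    angle_bounds = tuple(float(x) for x in range(0, 361, 10))
    rules = [
        BinningRule("table_angle", "numeric_interval", ANGLE_STATES,
                    angle_bounds),
        BinningRule("gantry_angle", "numeric_interval", ANGLE_STATES,
                    angle_bounds),
        BinningRule("collimator_angle", "numeric_interval", ANGLE_STATES,
                    angle_bounds),
        BinningRule("dose_per_fraction", "numeric_interval", DPF_STATES,
                    _DPF_BOUNDS),
        BinningRule("ptv_dose", "numeric_interval", PTV_STATES, _PTV_BOUNDS),
        BinningRule("number_of_fractions", "numeric_interval", NFX_STATES,
                    _NFX_BOUNDS),
        BinningRule("mu_per_cgy", "numeric_interval", MU_CGY_STATES,
                    _MU_CGY_BOUNDS),
        BinningRule("mu_per_degree", "numeric_interval", MU_DEG_STATES,
                    _MU_DEG_BOUNDS),
        BinningRule("ssd", "numeric_interval", SSD_STATES, _SSD_BOUNDS),
    ]
    for spec in default_schema():
        if spec.name not in {r.variable for r in rules}:
            rules.append(
                BinningRule(spec.name, "categorical_passthrough", spec.states)
            )
    return rules


#: Directed edges of the shipped structure: 24 nodes, 41 edges.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("tumor_site", "t_stage"),
    ("tumor_site", "n_stage"),
    ("tumor_site", "m_stage"),
    ("tumor_site", "treatment_intent"),
    ("m_stage", "treatment_intent"),
    ("tumor_site", "treatment_technique"),
    ("treatment_intent", "treatment_technique"),
    ("tumor_site", "patient_orientation"),
    ("tumor_site", "bolus"),
    ("radiation_type", "bolus"),
    ("tumor_site", "ptv_dose"),
    ("treatment_intent", "ptv_dose"),
    ("treatment_intent", "number_of_fractions"),
    ("ptv_dose", "number_of_fractions"),
    ("ptv_dose", "dose_per_fraction"),
    ("number_of_fractions", "dose_per_fraction"),
    ("tumor_site", "radiation_type"),
    ("treatment_technique", "radiation_type"),
    ("radiation_type", "beam_energy"),
    ("treatment_technique", "beam_energy"),
    ("treatment_technique", "number_of_beams"),
    ("tumor_site", "number_of_beams"),
    ("treatment_technique", "gantry_angle"),
    ("tumor_site", "gantry_angle"),
    ("treatment_technique", "collimator_angle"),
    ("treatment_technique", "wedge"),
    ("number_of_beams", "wedge"),
    ("patient_orientation", "table_angle"),
    ("treatment_technique", "table_angle"),
    ("tumor_site", "ssd"),
    ("treatment_technique", "ssd"),
    ("treatment_technique", "mu_per_cgy"),
    ("dose_per_fraction", "mu_per_cgy"),
    ("beam_energy", "mu_per_cgy"),
    ("treatment_technique", "mu_per_degree"),
    ("mu_per_cgy", "mu_per_degree"),
    ("treatment_intent", "image_guidance"),
    ("treatment_technique", "image_guidance"),
    ("treatment_technique", "dose_rate"),
    ("beam_energy", "dose_rate"),
    ("treatment_technique", "tolerance_table"),
)
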