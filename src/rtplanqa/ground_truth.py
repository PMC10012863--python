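"""Hand-authored ground-truth network for the synthetic cohort generator.

The conditional probability tables below encode broad radiotherapy practice
patterns (palliative intent favours short hypofractionated schedules, VMAT
plans are one or two arcs of 6 MV / FFF photons with daily CBCT, breast
3D-CRT uses opposed tangents, plan-complexity surrogates track technique,
and the prescription triplet dose-per-fraction x fractions ~ PTV dose is
arithmetically coherent).  They are synthetic: authored for dependency
structure, not fitted to any institution's data.
"""

from __future__ import annotations

import numpy as np

from .defaults import (
    default_schema,
    interval_bin,
    interval_representative,
    nfx_bin,
    nfx_representative,
    parse_interval,
)
from .network import CPT, BayesianNetwork, default_structure


# --- distribution helpers ---------------------------------------------------


def _dist(states, weights: dict[str, float], floor_total: float = 0.08):
    """Probability vector: ``weights`` (renormalized to 1 - floor_total)
    plus a uniform floor so every state stays reachable."""
    v = np.zeros(len(states))
    for s, w in weights.items():
        v[states.index(s)] += w
    if v.sum() <= 0:
        return np.full(len(states), 1.0 / len(states))
    v = v / v.sum() * (1.0 - floor_total)
    v += floor_total / len(states)
    return v


def _angle(states, peaks: dict[float, float], floor_total: float = 0.10):
    """Angle-bin distribution: each peak spreads 70/15/15 over its bin and
    the two wraparound neighbours."""
    w: dict[str, float] = {}
    nbins = len(states)
    for ang, wt in peaks.items():
        i = int(ang // 10) % nbins
        for j, frac in ((i, 0.70), ((i - 1) % nbins, 0.15),
                        ((i + 1) % nbins, 0.15)):
            w[states[j]] = w.get(states[j], 0.0) + wt * frac
    return _dist(states, w, floor_total)


def _shift(vec: np.ndarray, k: int) -> np.ndarray:
    """Shift probability mass ``k`` ordinal bins up (mass clipped at ends)."""
    out = np.zeros_like(vec)
    for i, p in enumerate(vec):
        out[min(max(i + k, 0), len(vec) - 1)] += p
    return out


# --- the network ------------------------------------------------------------


def base_network() -> BayesianNetwork:
    """Build the shared ground-truth network (structure + authored CPTs)."""
    schema = default_schema()
    structure = default_structure()
    st = {v.name: list(v.states) for v in schema}

    def D(states, weights, floor=0.08):
        return _dist(states, weights, floor)

    ptv_states = tuple(st["ptv_dose"])
    nfx_states = tuple(st["number_of_fractions"])
    dpf_states = tuple(st["dose_per_fraction"])

    dists: dict[str, callable] = {}

    dists["tumor_site"] = lambda: D(
        st["tumor_site"],
        {"breast": 0.24, "lung": 0.22, "prostate": 0.18, "head_neck": 0.12,
         "rectum": 0.10, "brain": 0.07, "bone_met": 0.07}, 0.0)

    t_by_site = {
        "breast": {"T0": 0.05, "T1": 0.40, "T2": 0.35, "T3": 0.12, "T4": 0.03, "Tx": 0.05},
        "lung": {"T1": 0.20, "T2": 0.30, "T3": 0.25, "T4": 0.15, "Tx": 0.10},
        "prostate": {"T1": 0.30, "T2": 0.40, "T3": 0.22, "T4": 0.05, "Tx": 0.03},
        "head_neck": {"T1": 0.12, "T2": 0.30, "T3": 0.30, "T4": 0.20, "Tx": 0.08},
        "rectum": {"T1": 0.05, "T2": 0.25, "T3": 0.45, "T4": 0.15, "Tx": 0.10},
        "brain": {"Tx": 0.80, "T1": 0.05, "T2": 0.05, "T3": 0.05, "T4": 0.05},
        "bone_met": {"Tx": 0.80, "T2": 0.05, "T3": 0.08, "T4": 0.07},
    }
    dists["t_stage"] = lambda site: D(st["t_stage"], t_by_site[site])

    n_by_site = {
        "breast": {"N0": 0.50, "N1": 0.30, "N2": 0.10, "N3": 0.05, "Nx": 0.05},
        "lung": {"N0": 0.35, "N1": 0.20, "N2": 0.30, "N3": 0.10, "Nx": 0.05},
        "prostate": {"N0": 0.80, "N1": 0.12, "Nx": 0.08},
        "head_neck": {"N0": 0.30, "N1": 0.25, "N2": 0.30, "N3": 0.10, "Nx": 0.05},
        "rectum": {"N0": 0.45, "N1": 0.35, "N2": 0.15, "Nx": 0.05},
        "brain": {"Nx": 0.85, "N0": 0.15},
        "bone_met": {"Nx": 0.70, "N0": 0.10, "N1": 0.20},
    }
    dists["n_stage"] = lambda site: D(st["n_stage"], n_by_site[site])

    m_by_site = {
        "breast": {"M0": 0.88, "M1": 0.08, "Mx": 0.04},
        "lung": {"M0": 0.68, "M1": 0.27, "Mx": 0.05},
        "prostate": {"M0": 0.90, "M1": 0.07, "Mx": 0.03},
        "head_neck": {"M0": 0.90, "M1": 0.06, "Mx": 0.04},
        "rectum": {"M0": 0.85, "M1": 0.12, "Mx": 0.03},
        "brain": {"M0": 0.45, "Mx": 0.50, "M1": 0.05},
        "bone_met": {"M1": 0.92, "M0": 0.03, "Mx": 0.05},
    }
    dists["m_stage"] = lambda site: D(st["m_stage"], m_by_site[site])

    def intent(site, m):
        if site == "bone_met":
            return D(st["treatment_intent"], {"palliative": 0.95, "curative": 0.05}, 0.02)
        if m == "M1":
            return D(st["treatment_intent"], {"palliative": 0.85, "curative": 0.15}, 0.02)
        return D(st["treatment_intent"], {"curative": 0.90, "palliative": 0.10}, 0.02)
    dists["treatment_intent"] = intent

    tech_by_site = {
        "breast": {"3dcrt": 0.50, "imrt": 0.30, "vmat": 0.15, "electron": 0.05},
        "lung": {"vmat": 0.60, "imrt": 0.25, "3dcrt": 0.15},
        "prostate": {"vmat": 0.75, "imrt": 0.20, "3dcrt": 0.05},
        "head_neck": {"vmat": 0.65, "imrt": 0.30, "3dcrt": 0.05},
        "rectum": {"vmat": 0.50, "imrt": 0.25, "3dcrt": 0.25},
        "brain": {"vmat": 0.60, "imrt": 0.25, "3dcrt": 0.15},
        "bone_met": {"3dcrt": 0.60, "vmat": 0.30, "imrt": 0.10},
    }

    def technique(site, it):
        if it == "palliative":
            return D(st["treatment_technique"],
                     {"3dcrt": 0.72, "vmat": 0.18, "imrt": 0.10})
        return D(st["treatment_technique"], tech_by_site[site])
    dists["treatment_technique"] = technique

    def rad_type(site, tech):
        if tech == "electron":
            return D(st["radiation_type"], {"electron": 0.97, "photon": 0.03}, 0.01)
        return D(st["radiation_type"], {"photon": 0.99, "electron": 0.01}, 0.01)
    dists["radiation_type"] = rad_type

    def energy(tech, rt):
        if rt == "electron":
            return D(st["beam_energy"], {"9MeV": 0.55, "12MeV": 0.40, "6MV": 0.05})
        if tech == "vmat":
            return D(st["beam_energy"], {"6MV": 0.55, "6FFF": 0.30, "10MV": 0.12, "15MV": 0.03})
        if tech == "imrt":
            return D(st["beam_energy"], {"6MV": 0.70, "10MV": 0.20, "6FFF": 0.05, "15MV": 0.05})
        return D(st["beam_energy"], {"6MV": 0.45, "10MV": 0.30, "15MV": 0.20, "6FFF": 0.05})
    dists["beam_energy"] = energy

    def n_beams(site, tech):
        if tech == "vmat":
            return D(st["number_of_beams"], {"2": 0.55, "1": 0.30, "3": 0.10, "4": 0.05})
        if tech == "electron":
            return D(st["number_of_beams"], {"1": 0.80, "2": 0.15, "3": 0.05})
        if tech == "3dcrt":
            if site == "breast":
                return D(st["number_of_beams"], {"2": 0.70, "3": 0.18, "4": 0.12})
            return D(st["number_of_beams"], {"2": 0.25, "3": 0.30, "4": 0.30, "1": 0.10, "5-7": 0.05})
        return D(st["number_of_beams"], {"5-7": 0.55, "8+": 0.25, "4": 0.15, "3": 0.05})
    dists["number_of_beams"] = n_beams

    def ssd(site, tech):
        if tech == "electron":
            return D(st["ssd"], {"[100,110)": 0.85, "[90,100)": 0.15})
        return D(st["ssd"], {"[90,100)": 0.68, "[80,90)": 0.22, "[70,80)": 0.07, "[100,110)": 0.03})
    dists["ssd"] = ssd

    def collimator(tech):
        if tech == "vmat":
            return _angle(st["collimator_angle"],
                          {15.0: 0.35, 345.0: 0.35, 30.0: 0.15, 0.0: 0.15})
        if tech == "imrt":
            return _angle(st["collimator_angle"], {0.0: 0.55, 15.0: 0.2, 350.0: 0.25})
        return _angle(st["collimator_angle"], {0.0: 0.85, 90.0: 0.15})
    dists["collimator_angle"] = collimator

    def gantry(site, tech):
        if tech == "vmat":
            return _angle(st["gantry_angle"], {180.0: 0.55, 179.0: 0.25, 0.0: 0.20})
        if tech == "electron":
            return _angle(st["gantry_angle"], {0.0: 0.60, 90.0: 0.2, 270.0: 0.2})
        if tech == "3dcrt" and site == "breast":
            return _angle(st["gantry_angle"], {305.0: 0.45, 125.0: 0.45, 0.0: 0.10})
        if tech == "imrt":
            return _angle(st["gantry_angle"],
                          {0.0: 0.30, 50.0: 0.15, 100.0: 0.15, 180.0: 0.15,
                           260.0: 0.1, 310.0: 0.15})
        return _angle(st["gantry_angle"], {0.0: 0.50, 180.0: 0.25, 90.0: 0.15, 270.0: 0.10})
    dists["gantry_angle"] = gantry

    def wedge(tech, nb):
        if tech == "3dcrt" and nb in ("2", "3"):
            return D(st["wedge"], {"none": 0.45, "physical": 0.30, "dynamic": 0.25}, 0.03)
        if tech == "3dcrt":
            return D(st["wedge"], {"none": 0.75, "physical": 0.12, "dynamic": 0.13}, 0.03)
        return D(st["wedge"], {"none": 0.94, "physical": 0.02, "dynamic": 0.04}, 0.03)
    dists["wedge"] = wedge

    def table(orient, tech):
        base = {0.0: 0.80, 350.0: 0.08}
        if tech in ("vmat", "imrt"):
            base[90.0] = 0.06
            base[270.0] = 0.06
        return _angle(st["table_angle"], base, 0.06)
    dists["table_angle"] = table

    def tol_table(tech):
        if tech == "electron":
            return D(st["tolerance_table"], {"electron": 0.80, "standard": 0.15, "clinical": 0.05})
        if tech == "vmat":
            return D(st["tolerance_table"], {"standard": 0.65, "sbrt": 0.25, "clinical": 0.10})
        return D(st["tolerance_table"], {"standard": 0.80, "clinical": 0.12, "sbrt": 0.08})
    dists["tolerance_table"] = tol_table

    def igrt(it, tech):
        if it == "palliative":
            return D(st["image_guidance"],
                     {"weekly_port": 0.40, "none": 0.30, "daily_kv": 0.20, "daily_cbct": 0.10})
        if tech == "vmat":
            return D(st["image_guidance"], {"daily_cbct": 0.80, "daily_kv": 0.15, "weekly_port": 0.05})
        if tech == "imrt":
            return D(st["image_guidance"], {"daily_cbct": 0.60, "daily_kv": 0.25, "weekly_port": 0.15})
        if tech == "electron":
            return D(st["image_guidance"], {"none": 0.55, "weekly_port": 0.35, "daily_kv": 0.10})
        return D(st["image_guidance"], {"weekly_port": 0.50, "daily_kv": 0.30, "daily_cbct": 0.15, "none": 0.05})
    dists["image_guidance"] = igrt

    def dose_rate(tech, en):
        if en == "6FFF":
            return D(st["dose_rate"], {"high": 0.85, "standard": 0.15}, 0.03)
        if tech == "vmat":
            return D(st["dose_rate"], {"standard": 0.70, "high": 0.25, "low": 0.05}, 0.03)
        return D(st["dose_rate"], {"standard": 0.85, "low": 0.10, "high": 0.05}, 0.03)
    dists["dose_rate"] = dose_rate

    ptv_by_site = {
        "breast": {"[4000,4500)": 0.50, "[5000,5500)": 0.30, "[2500,3000)": 0.08},
        "lung": {"[6000,6500)": 0.50, "[5000,5500)": 0.20, "[4500,5000)": 0.12},
        "prostate": {"[7500,8000)": 0.40, "[6000,6500)": 0.30, "[3500,4000)": 0.12},
        "head_neck": {"[6500,7000)": 0.45, "[7000,7500)": 0.25, "[6000,6500)": 0.15},
        "rectum": {"[4500,5000)": 0.50, "[5000,5500)": 0.25, "[2500,3000)": 0.10},
        "brain": {"[5500,6000)": 0.50, "[6000,6500)": 0.25, "[3000,3500)": 0.10},
        "bone_met": {"[3000,3500)": 0.45, "[2000,2500)": 0.30, "[500,1000)": 0.12},
    }

    def ptv(site, it):
        if it == "palliative":
            return D(ptv_states,
                     {"[3000,3500)": 0.45, "[2000,2500)": 0.30, "[500,1000)": 0.12,
                      "[1500,2000)": 0.08}, 0.06)
        return D(ptv_states, ptv_by_site[site], 0.06)
    dists["ptv_dose"] = ptv

    def nfractions(it, ptv_lab):
        rep = interval_representative(ptv_lab, 400.0)
        dpf_typ = 200.0 if it == "curative" else 350.0
        target = max(1, min(45, int(round(rep / dpf_typ))))
        center = nfx_bin(target, nfx_states)
        i = nfx_states.index(center)
        w = {center: 0.60}
        if i > 0:
            w[nfx_states[i - 1]] = 0.15
        if i < len(nfx_states) - 1:
            w[nfx_states[i + 1]] = 0.15
        return D(nfx_states, w, 0.06)
    dists["number_of_fractions"] = nfractions

    def dpf(ptv_lab, nfx_lab):
        rep = interval_representative(ptv_lab, 400.0)
        n = nfx_representative(nfx_lab)
        d = min(max(rep / n, 0.0), 599.0)
        center = interval_bin(d, dpf_states)
        i = dpf_states.index(center)
        w = {center: 0.72}
        if i > 0:
            w[dpf_states[i - 1]] = 0.09
        if i < len(dpf_states) - 1:
            w[dpf_states[i + 1]] = 0.09
        return D(dpf_states, w, 0.06)
    dists["dose_per_fraction"] = dpf

    mu_cgy_base = {
        "3dcrt": np.array([0.62, 0.25, 0.08, 0.03, 0.02]),
        "imrt": np.array([0.05, 0.18, 0.42, 0.25, 0.10]),
        "vmat": np.array([0.08, 0.40, 0.38, 0.10, 0.04]),
        "electron": np.array([0.55, 0.30, 0.10, 0.03, 0.02]),
    }

    def mu_cgy(tech, en, dpf_lab):
        v = mu_cgy_base[tech].copy()
        lo, _ = parse_interval(dpf_lab)
        if lo >= 400:  # hypofractionated / SBRT-like: more modulation per cGy
            v = _shift(v, 1)
        if en == "6FFF":
            v = _shift(v, 1)
        v = 0.92 * v / v.sum()
        return v + 0.08 / len(v)
    dists["mu_per_cgy"] = mu_cgy

    def mu_deg(tech, mu_lab):
        k = st["mu_per_cgy"].index(mu_lab)
        if tech == "vmat":
            v = np.zeros(5)
            v[k] = 0.60
            if k > 0:
                v[k - 1] = 0.20
            if k < 4:
                v[k + 1] = 0.20
        else:
            # fixed-gantry delivery: MU concentrated per degree
            v = np.array([0.02, 0.03, 0.10, 0.30, 0.55])
        v = 0.92 * v / v.sum()
        return v + 0.08 / len(v)
    dists["mu_per_degree"] = mu_deg

    orient_by_site = {
        "breast": {"head_first_supine": 0.78, "head_first_prone": 0.15, "feet_first_supine": 0.07},
        "rectum": {"head_first_supine": 0.60, "head_first_prone": 0.35, "feet_first_supine": 0.05},
        "prostate": {"head_first_supine": 0.90, "feet_first_supine": 0.08, "head_first_prone": 0.02},
    }

    def orientation(site):
        w = orient_by_site.get(
            site, {"head_first_supine": 0.92, "head_first_prone": 0.04,
                   "feet_first_supine": 0.04})
        return D(st["patient_orientation"], w, 0.03)
    dists["patient_orientation"] = orientation

    def bolus(site, rt):
        if rt == "electron":
            return D(st["bolus"], {"yes": 0.55, "no": 0.45}, 0.02)
        if site == "breast":
            return D(st["bolus"], {"no": 0.65, "yes": 0.35}, 0.02)
        if site == "head_neck":
            return D(st["bolus"], {"no": 0.80, "yes": 0.20}, 0.02)
        return D(st["bolus"], {"no": 0.95, "yes": 0.05}, 0.02)
    dists["bolus"] = bolus

    cpts: dict[str, CPT] = {}
    by_name = {v.name: v for v in schema}
    for node in structure.nodes:
        pars = structure.parents(node)
        pstates = [by_name[p].states for p in pars]
        shape = tuple(len(s) for s in pstates) + (len(by_name[node].states),)
        values = np.empty(shape)
        for combo in np.ndindex(*shape[:-1]):
            labels = [pstates[i][j] for i, j in enumerate(combo)]
            values[combo] = dists[node](*labels)
        cpts[node] = CPT(node, pars, values)
    net = BayesianNetwork(structure, cpts, schema)
    net.validate()
    return net
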