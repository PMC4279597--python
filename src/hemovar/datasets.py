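"""Bundled reference summary statistics.

Published group summaries (mean +/- SEM, n = 8 per group) from a study
of spontaneously hypertensive rats: intact hypertensive females (H),
hypertensive ovariectomized (HO), and hypertensive ovariectomized with
chronic fructose overload in the drinking water (FHO).  These numbers
serve two roles here: as inputs to the summary-statistics ANOVA/SNK
layer, and as calibration targets for the synthetic cohort and
recording generators.  No raw per-animal data accompany them.
"""

from __future__ import annotations

import pandas as pd

from .groupstats import GroupSummary

__all__ = [
    "GROUPS",
    "N_PER_GROUP",
    "metabolic_summary",
    "hemodynamics_summary",
    "inflammation_summary",
    "oxidative_summary",
    "intake_records",
    "row_summaries",
]

GROUPS = ("H", "HO", "FHO")
N_PER_GROUP = 8

# variable -> {group: (mean, sem)}
_METABOLIC = {
    "body_weight_g": {"H": (197, 2), "HO": (264, 3), "FHO": (261, 2)},
    "adipose_tissue_g": {"H": (1.91, 0.16), "HO": (2.96, 0.45), "FHO": (5.25, 0.39)},
    "glucose_mg_dl": {"H": (83, 5.0), "HO": (84, 2.0), "FHO": (92, 2.1)},
    "triglyceride_mg_dl": {"H": (132, 4.0), "HO": (125, 6.4), "FHO": (160, 8.0)},
    "kitt_pct_min": {"H": (4.15, 0.26), "HO": (4.69, 0.33), "FHO": (3.4, 0.28)},
}

_HEMODYNAMICS = {
    "sap_mmhg": {"H": (174, 5), "HO": (183, 6), "FHO": (206, 4)},
    "dap_mmhg": {"H": (121, 7), "HO": (144, 5), "FHO": (153, 2)},
    "map_mmhg": {"H": (146, 6), "HO": (164, 5), "FHO": (174, 4)},
    "hr_bpm": {"H": (352, 13), "HO": (348, 16), "FHO": (403, 12)},
    "pi_sd_ms": {"H": (6.62, 0.61), "HO": (8.63, 1.00), "FHO": (5.43, 0.96)},
    "pi_var_ms2": {"H": (53.97, 7.98), "HO": (63.64, 10.34), "FHO": (30.84, 6.81)},
    "pi_lf_ms2": {"H": (3.18, 0.55), "HO": (3.94, 0.97), "FHO": (0.90, 0.12)},
    "pi_hf_ms2": {"H": (5.97, 1.41), "HO": (9.22, 2.03), "FHO": (2.77, 0.18)},
    "sap_var_mmhg2": {"H": (31.08, 2.66), "HO": (51.94, 6.94), "FHO": (77.79, 11.87)},
    "sap_lf_mmhg2": {"H": (5.06, 0.91), "HO": (5.07, 0.52), "FHO": (10.62, 2.33)},
}

_INFLAMMATION = {
    "tnf_alpha_pg_mg": {"H": (32.9, 7.5), "HO": (31.7, 8.6), "FHO": (65.8, 9.9)},
    "il6_pg_mg": {"H": (379, 27), "HO": (368, 26), "FHO": (401, 35)},
    "il10_pg_mg": {"H": (37.1, 9.0), "HO": (29.6, 3.4), "FHO": (16.2, 2.5)},
}

_OXIDATIVE = {
    "tbars_umol_mg": {"H": (4.95, 0.89), "HO": (8.27, 0.98), "FHO": (12.03, 0.93)},
    "cl_cps_mg": {"H": (6661, 566), "HO": (6514, 547), "FHO": (15043, 1333)},
    "cat_nmol_mg": {"H": (0.29, 0.04), "HO": (0.47, 0.05), "FHO": (0.63, 0.05)},
    "sod_u_mg": {"H": (11.47, 0.37), "HO": (11.17, 0.41), "FHO": (13.05, 0.86)},
    "gpx_nmol_min_mg": {"H": (54.78, 3.10), "HO": (38.55, 1.67), "FHO": (63.39, 5.52)},
    "gsh_gssg": {"H": (11.07, 0.7), "HO": (13.00, 1.4), "FHO": (8.94, 0.8)},
}

# mean daily consumption per group: chow g/day, fluid mL/day, fructose g/L
_INTAKE = {
    "H": {"chow": 16.8, "fluid": 25.2, "fructose_conc": 0.0},
    "HO": {"chow": 11.5, "fluid": 24.6, "fructose_conc": 0.0},
    "FHO": {"chow": 14.0, "fluid": 82.9, "fructose_conc": 100.0},
}
# reported total caloric intake (kcal/day) for the same groups
REPORTED_KCAL = {"H": 48.7, "HO": 33.3, "FHO": 73.7}


def _table(data: dict) -> pd.DataFrame:
    rows = [
        {"variable": var, "group": g, "mean": m, "sem": s, "n": N_PER_GROUP}
        for var, per_group in data.items()
        for g, (m, s) in per_group.items()
    ]
    return pd.DataFrame(rows)


def metabolic_summary() -> pd.DataFrame:
    """Body weight, adiposity, glycemia, triglycerides and KITT."""
    return _table(_METABOLIC)


def hemodynamics_summary() -> pd.DataFrame:
    """Arterial pressures, heart rate, and HRV/BPV indices."""
    return _table(_HEMODYNAMICS)


def inflammation_summary() -> pd.DataFrame:
    """Cardiac TNF-alpha, IL-6 and IL-10."""
    return _table(_INFLAMMATION)


def oxidative_summary() -> pd.DataFrame:
    """Cardiac oxidative-stress markers."""
    return _table(_OXIDATIVE)


def intake_records() -> dict[str, dict[str, float]]:
    """Mean chow/fluid consumption per group, with the fructose
    concentration of the drinking fluid."""
    return {g: dict(v) for g, v in _INTAKE.items()}


def row_summaries(table: pd.DataFrame, variable: str) -> list[GroupSummary]:
    """One table row as GroupSummary objects, in group order."""
    sub = table[table["variable"] == variable]
    if sub.empty:
        raise KeyError(f"unknown variable {variable!r}")
    by_group = {r["group"]: r for _, r in sub.iterrows()}
    return [
        GroupSummary(label=g, mean=by_group[g]["mean"], sem=by_group[g]["sem"], n=int(by_group[g]["n"]))
        for g in GROUPS
        if g in by_group
    ]
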