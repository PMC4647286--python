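"""Per-patient index-year cost assembly and category summaries.

Individual-level costs are assembled by multiplying resource use with unit
costs. Each resource item maps to exactly one of eight reporting categories
(pressure wire, PCI, CABG, medications, cath-lab time, length of stay, other
procedures, events during the index year); the pressure wire in the
angiography-only arm is protocol-driven and stripped before costing.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import COST_CATEGORIES, UnitCostTable, load_unit_costs

# resource column -> (category, unit-cost item). A unit-cost item of None
# means the column already holds a GBP amount.
RESOURCE_MAP: dict[str, tuple[str, Optional[str]]] = {
    "wires": ("pressure_wire", "pressure_wire"),
    "adenosine_vials": ("pressure_wire", "adenosine_vial"),
    "guiding_catheters": ("pci", "guiding_catheter"),
    "guidewires": ("pci", "guidewire"),
    "balloons": ("pci", "balloon"),
    "des_stents": ("pci", "des_stent"),
    "bms_stents": ("pci", "bms_stent"),
    "cabg_performed": ("cabg", "cabg"),
    "tirofiban_gbp": ("medications", None),
    "bivalirudin_gbp": ("medications", None),
    "clopidogrel_months": ("medications", "clopidogrel_month"),
    "cathlab_hours": ("cath_lab", "cathlab_hour"),
    "ccu_days": ("length_of_stay", "ccu_day"),
    "itu_days": ("length_of_stay", "itu_day"),
    "ward_days": ("length_of_stay", "ward_day"),
    "echos": ("other_procedures", "echo"),
    "oct": ("other_procedures", "oct"),
    "ivus": ("other_procedures", "ivus"),
    "xrays": ("other_procedures", "xray"),
    "rehospitalisations": ("events", "rehospitalisation"),
    "revascularisations": ("events", "revascularisation"),
    "mi_events": ("events", "mi_event"),
    "strokes": ("events", "stroke_index_year"),
    "severe_bleeds": ("events", "severe_bleed"),
}


def resource_map(adenosine_category: str = "pressure_wire") -> dict[str, tuple[str, Optional[str]]]:
    """The item -> category mapping; adenosine may be re-homed to medications."""
    if adenosine_category not in ("pressure_wire", "medications"):
        raise ValueError("adenosine_category must be 'pressure_wire' or 'medications'")
    m = dict(RESOURCE_MAP)
    m["adenosine_vials"] = (adenosine_category, "adenosine_vial")
    return m


def strip_protocol_costs(table: pd.DataFrame) -> pd.DataFrame:
    """Zero the protocol-driven pressure wire (and its adenosine) in the
    angiography-only arm. Idempotent; every other entry is unchanged."""
    out = table.copy()
    std = out["arm"] == "standard"
    for col in ("wires", "adenosine_vials"):
        if col in out.columns:
            out.loc[std, col] = 0.0
    return out


def assemble_costs(
    profile: Union[pd.DataFrame, pd.Series, dict],
    unit_costs: Optional[UnitCostTable] = None,
    adenosine_category: str = "pressure_wire",
) -> pd.DataFrame:
    """Linear resource-use x unit-cost assembly into the 8 reporting
    categories plus a total.

    Accepts a full patient table or a single resource profile. Any resource
    column not in the category mapping raises a KeyError naming the item.
    Identifier columns (id, arm) are carried through when present.
    """
    if unit_costs is None:
        unit_costs = load_unit_costs()
    if isinstance(profile, dict):
        profile = pd.Series(profile)
    if isinstance(profile, pd.Series):
        table = profile.to_frame().T
    else:
        table = profile
    rmap = resource_map(adenosine_category)

    known_other = {
        "id", "arm", "age", "sex", "smoker", "prior_pci", "copd", "decision",
        "mace", "mace_event", "death_time", "utility_0", "utility_6m", "utility_12m",
    }
    out = pd.DataFrame(index=table.index)
    for meta in ("id", "arm"):
        if meta in table.columns:
            out[meta] = table[meta]
    cats = {cat: np.zeros(len(table)) for cat in COST_CATEGORIES}
    for col in table.columns:
        if col in known_other:
            continue
        if col not in rmap:
            raise KeyError(f"unknown resource item {col!r}: no cost-category mapping")
        cat, item = rmap[col]
        qty = table[col].to_numpy(dtype=float)
        if np.any(qty < 0):
            raise ValueError(f"negative quantity in resource item {col!r}")
        cats[cat] += qty * (1.0 if item is None else unit_costs.mean(item))
    for cat in COST_CATEGORIES:
        out[cat] = cats[cat]
    out["total"] = sum(cats.values())
    return out


def summarise_costs(
    cost_table: pd.DataFrame, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Arm-level category means with bootstrap percentile 95% CIs and
    FFR - standard differences.

    Patients are resampled with replacement within arm; differences are
    resampled jointly. Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    rows = list(COST_CATEGORIES) + ["total"]
    arms = {}
    for arm in ("standard", "ffr"):
        sub = cost_table.loc[cost_table["arm"] == arm, rows].to_numpy(dtype=float)
        if len(sub) == 0:
            raise ValueError(f"arm {arm!r} is empty")
        arms[arm] = sub
    boot = {arm: np.empty((n_boot, len(rows))) for arm in arms}
    for b in range(n_boot):
        for arm, sub in arms.items():
            idx = rng.integers(0, len(sub), len(sub))
            boot[arm][b] = sub[idx].mean(axis=0)
    diff_boot = boot["ffr"] - boot["standard"]

    out = pd.DataFrame(index=rows)
    for arm, sub in arms.items():
        out[f"mean_{arm}"] = sub.mean(axis=0)
        lo, hi = np.percentile(boot[arm], [2.5, 97.5], axis=0)
        out[f"ci_low_{arm}"] = lo
        out[f"ci_high_{arm}"] = hi
    out["difference"] = out["mean_ffr"] - out["mean_standard"]
    lo, hi = np.percentile(diff_boot, [2.5, 97.5], axis=0)
    out["ci_low_difference"] = lo
    out["ci_high_difference"] = hi
    out.index.name = "category"
    return out
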