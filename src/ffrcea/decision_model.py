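"""Decision-tree evaluation over trial and lifetime horizons.

The tree branches on the treatment decision (MT, PCI, CABG) and, within each
decision, on incident MACE during the index year. Expected index-year cost is
the probability-weighted sum over the six (decision x MACE) cells plus the
pressure-wire add-on in the FFR arm; trial QALYs enter unstructured at the
arm level (the tree structure is imposed on costs and MACE only). Beyond
year 1 a common cost and utility tariff, conditioned on index-year MACE, is
applied over the remaining (discounted) life expectancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ARMS, DECISIONS, DecisionModelParams


def apply_or(baseline_risk, odds_ratio):
    """Convert a baseline risk to the risk implied by an odds ratio:
    odds = risk/(1-risk); risk' = OR*odds / (1 + OR*odds).

    Accepts scalars or numpy arrays.
    """
    b = np.asarray(baseline_risk, dtype=float)
    o = np.asarray(odds_ratio, dtype=float)
    if np.any(b <= 0) or np.any(b >= 1):
        raise ValueError(f"baseline risk must lie strictly in (0, 1), got {baseline_risk}")
    if np.any(o <= 0):
        raise ValueError(f"odds ratio must be > 0, got {odds_ratio}")
    odds = b / (1.0 - b) * o
    risk = odds / (1.0 + odds)
    return float(risk) if np.isscalar(baseline_risk) and np.isscalar(odds_ratio) else risk


def discounted_years(total_years: float, rate: float, start_year: int = 2) -> np.ndarray:
    """Per-year discount weights for an extension of *total_years* beyond the
    trial year. Year t contributes (1+rate)^-(t-1); the trial year (t = 1)
    carries weight 1 and is excluded; the final fractional year is pro-rata.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if total_years < 0:
        raise ValueError(f"total_years must be >= 0, got {total_years}")
    if total_years == 0:
        return np.array([])
    full = int(np.floor(total_years))
    frac = total_years - full
    years = np.arange(start_year, start_year + full + (1 if frac > 1e-12 else 0))
    w = (1.0 + rate) ** -(years - 1.0)
    if frac > 1e-12:
        w[-1] *= frac
    return w


def discounted_year_sum(total_years, rate: float, start_year: int = 2):
    """Vectorised closed form of ``discounted_years(...).sum()``."""
    L = np.asarray(total_years, dtype=float)
    if np.any(L < 0):
        raise ValueError("total_years must be >= 0")
    if rate == 0:
        out = L
    else:
        v = 1.0 / (1.0 + rate)
        full = np.floor(L)
        frac = L - full
        base = v ** (start_year - 2)  # weight of the first extension year / v
        out = base * (v * (1.0 - v**full) / (1.0 - v) + frac * v ** (full + 1))
    return float(out) if np.isscalar(total_years) else out


@dataclass
class ArmResult:
    """Expected per-patient results for one arm."""

    trial_cost: float
    trial_qaly: float
    lifetime_cost: float
    lifetime_qaly: float
    p_mace: float


def lifetime_extension(mace: bool, params: DecisionModelParams) -> tuple[float, float]:
    """(additional discounted cost, additional discounted QALYs) beyond the
    index year, conditional on index-year MACE status."""
    le_mace, le_no_mace = params.life_expectancies()
    years = le_mace if mace else le_no_mace
    w = discounted_years(years, params.discount_rate)
    if len(w) == 0:
        return 0.0, 0.0
    cost = params.annual_cost_post_year1.mean * float(w.sum())
    # age during extension year k (k = 0, 1, ...) is starting_age + 1 + k
    ages = params.starting_age + 1.0 + np.arange(len(w))
    decrement = params.mace_utility_decrement.mean if mace else 0.0
    utils = np.clip(params.utility_schedule(ages) + decrement, 0.0, None)
    return cost, float(np.dot(w, utils))


def evaluate_tree(params: DecisionModelParams, arm: str) -> tuple[float, float, float]:
    """Trial-horizon (expected cost, expected QALY, MACE probability)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    probs = np.asarray(params.treatment_probs[arm], dtype=float)
    base = params.mace_mt.mean
    if base == 0.0:  # degenerate no-MACE tree
        risks = np.zeros(3)
    else:
        risks = np.array(
            [base, apply_or(base, params.or_pci.mean), apply_or(base, params.or_cabg.mean)]
        )
    cost = 0.0
    for p, r, dec in zip(probs, risks, DECISIONS):
        for status, weight in (("mace", r), ("no_mace", 1.0 - r)):
            cell = f"{dec}_{status}"
            if cell not in params.branch_costs:
                raise ValueError(f"missing branch cost for cell {cell!r}")
            cost += p * weight * params.branch_costs[cell].mean
    if arm == "ffr":
        cost += params.wire_cost_ffr.mean
    p_mace = float(np.dot(probs, risks))
    qaly = params.branch_qalys[arm].mean
    return float(cost), float(qaly), p_mace


def run_model(params: DecisionModelParams) -> dict:
    """Evaluate both arms over both horizons and form FFR - standard increments."""
    results: dict = {}
    for arm in ARMS:
        cost, qaly, p_mace = evaluate_tree(params, arm)
        ext_cost_m, ext_qaly_m = lifetime_extension(True, params)
        ext_cost_n, ext_qaly_n = lifetime_extension(False, params)
        results[arm] = ArmResult(
            trial_cost=cost,
            trial_qaly=qaly,
            lifetime_cost=cost + p_mace * ext_cost_m + (1 - p_mace) * ext_cost_n,
            lifetime_qaly=qaly + p_mace * ext_qaly_m + (1 - p_mace) * ext_qaly_n,
            p_mace=p_mace,
        )
    ffr, std = results["ffr"], results["standard"]
    results["incremental"] = {
        "trial_cost": ffr.trial_cost - std.trial_cost,
        "trial_qaly": ffr.trial_qaly - std.trial_qaly,
        "lifetime_cost": ffr.lifetime_cost - std.lifetime_cost,
        "lifetime_qaly": ffr.lifetime_qaly - std.lifetime_qaly,
    }
    return results
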