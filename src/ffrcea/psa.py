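"""Probabilistic sensitivity analysis.

Parameter distributions are calibrated by method of moments to printed
mean/SE pairs (beta for utilities and probabilities, gamma for costs,
lognormal for odds ratios matched to their printed 95% CI, Dirichlet for the
three rival treatment decisions, normal for life expectancies). Each PSA
replicate samples every uncertain parameter, evaluates the decision tree for
both arms and horizons, and records incremental cost/QALY pairs, from which
the ICER, cost-effectiveness plane and acceptability curves follow.

Two uncertainty modes are supported: ``parameters_only`` (distribution draws
alone) and ``parameters_plus_bootstrap`` (each replicate additionally
resamples the patient table and refits the statistical models, combining
sampling and parameter uncertainty in a single loop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ARMS, DECISIONS, DecisionModelParams, ParamWithSE, UnitCostTable, load_unit_costs
from .costing import assemble_costs, strip_protocol_costs
from .decision_model import apply_or
from .outcomes import qaly_table
from .regression import (
    COST_SPEC_PREDICTORS,
    DECISION_TERM,
    MACE_SPEC_PREDICTORS,
    GlmSpec,
    fit_glm,
    fit_logistic,
    marginal_predict,
)


# ---------------------------------------------------------------------------
# distribution calibration

@dataclass
class DistributionSpec:
    """A calibrated sampling distribution with its source moments."""

    kind: str
    params: dict
    mean: float
    se: float
    sign: float = 1.0

    def sample(self, rng: np.random.Generator, size=None):
        p = self.params
        if self.kind == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "gamma":
            return self.sign * rng.gamma(p["shape"], p["scale"], size)
        if self.kind == "beta":
            return self.sign * rng.beta(p["alpha"], p["beta"], size)
        if self.kind == "normal":
            if p.get("truncate_at_zero"):
                a = (0.0 - p["loc"]) / p["scale"]
                return stats.truncnorm.rvs(a, np.inf, loc=p["loc"], scale=p["scale"], size=size, random_state=rng)
            return rng.normal(p["loc"], p["scale"], size)
        if self.kind == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def analytic_mean(self) -> float:
        p = self.params
        if self.kind == "fixed":
            return self.mean
        if self.kind == "gamma":
            return self.sign * p["shape"] * p["scale"]
        if self.kind == "beta":
            return self.sign * p["alpha"] / (p["alpha"] + p["beta"])
        if self.kind == "normal":
            return p["loc"]
        if self.kind == "lognormal":
            return math.exp(p["mu"] + p["sigma"] ** 2 / 2)
        raise ValueError(self.kind)

    def analytic_sd(self) -> float:
        p = self.params
        if self.kind == "fixed":
            return 0.0
        if self.kind == "gamma":
            return math.sqrt(p["shape"]) * p["scale"]
        if self.kind == "beta":
            a, b = p["alpha"], p["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.kind == "normal":
            return p["scale"]
        if self.kind == "lognormal":
            s2 = p["sigma"] ** 2
            return math.sqrt((math.exp(s2) - 1.0)) * math.exp(p["mu"] + s2 / 2)
        raise ValueError(self.kind)


def calibrate_distribution(
    mean: float, se: float, kind: str, truncate_at_zero: bool = False
) -> DistributionSpec:
    """Method-of-moments calibration. Beta distributions are applied to the
    magnitude of negative quantities (sign restored on sampling)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0 or kind == "fixed":
        return DistributionSpec("fixed", {}, mean, 0.0)
    if kind == "gamma":
        sign = 1.0 if mean >= 0 else -1.0
        m = abs(mean)
        if m == 0:
            raise ValueError("gamma calibration needs a nonzero mean")
        return DistributionSpec("gamma", {"shape": (m / se) ** 2, "scale": se**2 / m}, mean, se, sign)
    if kind == "beta":
        sign = 1.0 if mean >= 0 else -1.0
        m = abs(mean)
        if not (0 < m < 1):
            raise ValueError(f"beta calibration needs |mean| in (0, 1), got {mean}")
        nu = m * (1 - m) / se**2 - 1.0
        if nu <= 0:
            raise ValueError(f"beta calibration impossible: SE {se} too large for mean {mean}")
        return DistributionSpec("beta", {"alpha": m * nu, "beta": (1 - m) * nu}, mean, se, sign)
    if kind == "normal":
        return DistributionSpec(
            "normal", {"loc": mean, "scale": se, "truncate_at_zero": truncate_at_zero}, mean, se
        )
    if kind == "lognormal":
        if mean <= 0:
            raise ValueError("lognormal calibration needs mean > 0")
        s2 = math.log(1.0 + (se / mean) ** 2)
        return DistributionSpec(
            "lognormal", {"mu": math.log(mean) - s2 / 2, "sigma": math.sqrt(s2)}, mean, se
        )
    raise ValueError(f"unknown distribution kind {kind!r}")


def calibrate_lognormal_from_ci(point: float, ci_low: float, ci_high: float) -> DistributionSpec:
    """Lognormal for a ratio parameter: log-scale SE from the 95% CI width."""
    if min(point, ci_low, ci_high) <= 0 or ci_high <= ci_low:
        raise ValueError("need 0 < ci_low < ci_high and point > 0")
    sigma = math.log(ci_high / ci_low) / (2 * stats.norm.ppf(0.975))
    return DistributionSpec("lognormal", {"mu": math.log(point), "sigma": sigma}, point, sigma)


def calibrate_dirichlet(
    means, ses, honour: Optional[int] = None
) -> np.ndarray:
    """Dirichlet alphas for >2 rival events from per-category means and SEs.

    The effective sample size N is chosen by least squares over the implied
    per-category SEs sqrt(p(1-p)/(N+1)); with *honour* set, N matches that
    category's SE exactly (N = p(1-p)/se^2 - 1). alpha_i = N * mean_i.
    """
    p = np.asarray(means, dtype=float)
    s = np.asarray(ses, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"means must sum to 1, got {p.sum()}")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("degenerate Dirichlet: every mean must lie strictly in (0, 1)")
    if honour is not None:
        n_eff = p[honour] * (1 - p[honour]) / s[honour] ** 2 - 1.0
    else:
        def loss(n):
            return float(np.sum((s - np.sqrt(p * (1 - p) / (n + 1.0))) ** 2))

        n_eff = optimize.minimize_scalar(loss, bounds=(1.0, 1e7), method="bounded").x
    if n_eff <= 0:
        raise ValueError("implied Dirichlet sample size is non-positive")
    return n_eff * p


# ---------------------------------------------------------------------------
# refit of trial-derived parameters from a patient table

def derive_model_params(
    patients: pd.DataFrame,
    base_params: DecisionModelParams,
    unit_costs: Optional[UnitCostTable] = None,
) -> DecisionModelParams:
    """Re-derive the trial-based decision-model inputs from individual-level
    data: decision frequencies, branch costs by marginal prediction from the
    cost GLM, MACE baseline and odds ratios from the logistic model, raw arm
    QALYs, and the FFR pressure-wire cost.

    The patient table must have complete utilities (impute first).
    """
    if unit_costs is None:
        unit_costs = load_unit_costs()
    work = patients.copy()
    work["mace"] = work["mace"].astype(int)

    costs = assemble_costs(strip_protocol_costs(work), unit_costs)
    work["total_cost"] = costs["total"].to_numpy()
    # wire add-on modelled separately from the tree's branch costs
    work["tree_cost"] = work["total_cost"] - costs["pressure_wire"].to_numpy()

    cost_fit = fit_glm(work, GlmSpec("tree_cost", COST_SPEC_PREDICTORS, "gamma", "log"))
    branch_costs = {}
    for dec in DECISIONS:
        for status, val in (("mace", 1), ("no_mace", 0)):
            w2 = work.copy()
            w2["mace"] = val
            branch_costs[f"{dec}_{status}"] = ParamWithSE(
                mean=marginal_predict(cost_fit, w2, "decision", dec), se=0.0
            )

    mace_fit, ors = fit_logistic(work, GlmSpec("mace", MACE_SPEC_PREDICTORS))
    mt_prob = marginal_predict(mace_fit, work, "decision", "MT")
    or_pci = float(ors.loc[f"{DECISION_TERM}[T.PCI]", "odds_ratio"])
    or_cabg = float(ors.loc[f"{DECISION_TERM}[T.CABG]", "odds_ratio"])

    qalys = qaly_table(work)
    branch_qalys = {
        arm: ParamWithSE(mean=float(qalys[work["arm"] == arm].mean()), se=0.0) for arm in ARMS
    }
    tp = {}
    for arm in ARMS:
        counts = work.loc[work["arm"] == arm, "decision"].value_counts()
        n = counts.sum()
        tp[arm] = tuple(float(counts.get(d, 0)) / n for d in DECISIONS)
    wire_mean = float(costs.loc[(work["arm"] == "ffr").to_numpy(), "pressure_wire"].mean())

    return base_params.model_copy(
        update={
            "treatment_probs": tp,
            "mace_mt": ParamWithSE(mean=mt_prob, se=base_params.mace_mt.se),
            "or_pci": base_params.or_pci.model_copy(update={"mean": or_pci}),
            "or_cabg": base_params.or_cabg.model_copy(update={"mean": or_cabg}),
            "branch_costs": branch_costs,
            "branch_qalys": branch_qalys,
            "wire_cost_ffr": ParamWithSE(mean=wire_mean, se=base_params.wire_cost_ffr.se),
        }
    )


# ---------------------------------------------------------------------------
# the PSA proper

@dataclass
class PsaDraws:
    """Per-replicate incremental costs and QALYs (FFR - standard)."""

    dc_trial: np.ndarray
    de_trial: np.ndarray
    dc_life: np.ndarray
    de_life: np.ndarray
    n_draws: int
    seed: int
    mode: str
    param_draws: dict = field(default_factory=dict)
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "dc_trial": self.dc_trial,
                "de_trial": self.de_trial,
                "dc_life": self.dc_life,
                "de_life": self.de_life,
            }
        )


def build_distributions(params: DecisionModelParams) -> dict:
    """Calibrate every uncertain decision-model parameter."""
    def _or_dist(p):
        if abs(p.ci_high - p.ci_low) < 1e-12:
            return DistributionSpec("fixed", {}, p.mean, 0.0)
        return calibrate_lognormal_from_ci(p.mean, p.ci_low, p.ci_high)

    dists = {
        "mace_mt": calibrate_distribution(params.mace_mt.mean, params.mace_mt.se, "beta"),
        "or_pci": _or_dist(params.or_pci),
        "or_cabg": _or_dist(params.or_cabg),
        "wire_cost_ffr": calibrate_distribution(
            params.wire_cost_ffr.mean, params.wire_cost_ffr.se, "gamma"
        ),
        "life_expectancy_mace": calibrate_distribution(
            params.life_expectancy_mace.mean, params.life_expectancy_mace.se, "normal", truncate_at_zero=True
        ),
        "life_expectancy_no_mace": calibrate_distribution(
            params.life_expectancy_no_mace.mean, params.life_expectancy_no_mace.se, "normal", truncate_at_zero=True
        ),
        "annual_cost_post_year1": calibrate_distribution(
            params.annual_cost_post_year1.mean, params.annual_cost_post_year1.se, "gamma"
        ),
        "mace_utility_decrement": calibrate_distribution(
            params.mace_utility_decrement.mean, params.mace_utility_decrement.se, "beta"
        ),
    }
    for cell, pse in params.branch_costs.items():
        dists[f"cost_{cell}"] = calibrate_distribution(pse.mean, pse.se, "gamma")
    for arm in ARMS:
        q = params.branch_qalys[arm]
        dists[f"qaly_{arm}"] = calibrate_distribution(q.mean, q.se, "beta")
        dists[f"dirichlet_{arm}"] = calibrate_dirichlet(
            params.treatment_probs[arm], params.treatment_prob_ses[arm]
        )
    return dists


def _extension_sums(years: np.ndarray, params: DecisionModelParams, decrement: np.ndarray):
    """Vectorised discounted year-sums and QALY-sums for the extension."""
    v = 1.0 / (1.0 + params.discount_rate)
    kmax = int(np.ceil(max(years.max(), 1.0)))
    k = np.arange(kmax)
    frac = np.clip(years[:, None] - k[None, :], 0.0, 1.0)
    w = frac * v ** (k[None, :] + 1)
    ages = params.starting_age + 1.0 + k
    u = np.clip(params.utility_schedule(ages)[None, :] + decrement[:, None], 0.0, None)
    return w.sum(axis=1), (w * u).sum(axis=1)


def run_psa(
    params: DecisionModelParams,
    n_draws: int = 10_000,
    seed: int = 0,
    mode: str = "parameters_only",
    patients: Optional[pd.DataFrame] = None,
    unit_costs: Optional[UnitCostTable] = None,
    identity_resample: bool = False,
) -> PsaDraws:
    """Propagate parameter (and optionally sampling) uncertainty through the
    decision tree. Deterministic given *seed*."""
    if mode not in ("parameters_only", "parameters_plus_bootstrap"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    dists = build_distributions(params)

    probs = {}
    for arm in ARMS:
        if all(se == 0 for se in params.treatment_prob_ses[arm]):
            probs[arm] = np.tile(np.asarray(params.treatment_probs[arm]), (n_draws, 1))
        else:
            probs[arm] = rng.dirichlet(dists[f"dirichlet_{arm}"], n_draws)
    mace_mt = dists["mace_mt"].sample(rng, n_draws)
    or_pci = dists["or_pci"].sample(rng, n_draws)
    or_cabg = dists["or_cabg"].sample(rng, n_draws)
    cell_costs = {
        cell: dists[f"cost_{cell}"].sample(rng, n_draws) for cell in params.branch_costs
    }
    wire = dists["wire_cost_ffr"].sample(rng, n_draws)
    qalys = {arm: dists[f"qaly_{arm}"].sample(rng, n_draws) for arm in ARMS}
    le_mace_d = dists["life_expectancy_mace"].sample(rng, n_draws)
    le_no_d = dists["life_expectancy_no_mace"].sample(rng, n_draws)
    if params.swap_life_expectancy:
        le_mace_d, le_no_d = le_no_d, le_mace_d
    annual = dists["annual_cost_post_year1"].sample(rng, n_draws)
    decrement = dists["mace_utility_decrement"].sample(rng, n_draws)

    n_redrawn = 0
    if mode == "parameters_plus_bootstrap":
        if patients is None:
            raise ValueError("bootstrap mode requires a patient table")
        if unit_costs is None:
            unit_costs = load_unit_costs()
        by_arm = {arm: patients[patients["arm"] == arm] for arm in ARMS}
        for b in range(n_draws):
            attempts = 0
            while True:
                try:
                    if identity_resample:
                        resampled = patients
                    else:
                        parts = []
                        for arm in ARMS:
                            sub = by_arm[arm]
                            idx = rng.integers(0, len(sub), len(sub))
                            parts.append(sub.iloc[idx])
                        resampled = pd.concat(parts, ignore_index=True)
                    derived = derive_model_params(resampled, params, unit_costs)
                    break
                except RuntimeError:
                    attempts += 1
                    n_redrawn += 1
                    if attempts > 20:
                        raise
            for arm in ARMS:
                probs[arm][b] = derived.treatment_probs[arm]
                qalys[arm][b] = derived.branch_qalys[arm].mean
            mace_mt[b] = derived.mace_mt.mean
            or_pci[b] = derived.or_pci.mean
            or_cabg[b] = derived.or_cabg.mean
            wire[b] = derived.wire_cost_ffr.mean
            for cell in cell_costs:
                cell_costs[cell][b] = derived.branch_costs[cell].mean

    # vectorised tree evaluation
    risks = {
        "MT": mace_mt,
        "PCI": apply_or(mace_mt, or_pci),
        "CABG": apply_or(mace_mt, or_cabg),
    }
    ext_cost_m, ext_qaly_m = _extension_sums(le_mace_d, params, decrement)
    ext_cost_n, ext_qaly_n = _extension_sums(le_no_d, params, np.zeros(n_draws))
    ext_cost_m, ext_cost_n = annual * ext_cost_m, annual * ext_cost_n

    arm_res = {}
    for arm in ARMS:
        cost = np.zeros(n_draws)
        p_mace = np.zeros(n_draws)
        for j, dec in enumerate(DECISIONS):
            r = risks[dec]
            cost += probs[arm][:, j] * (
                r * cell_costs[f"{dec}_mace"] + (1 - r) * cell_costs[f"{dec}_no_mace"]
            )
            p_mace += probs[arm][:, j] * r
        if arm == "ffr":
            cost = cost + wire
        life_cost = cost + p_mace * ext_cost_m + (1 - p_mace) * ext_cost_n
        life_qaly = qalys[arm] + p_mace * ext_qaly_m + (1 - p_mace) * ext_qaly_n
        arm_res[arm] = (cost, qalys[arm], life_cost, life_qaly)

    return PsaDraws(
        dc_trial=arm_res["ffr"][0] - arm_res["standard"][0],
        de_trial=arm_res["ffr"][1] - arm_res["standard"][1],
        dc_life=arm_res["ffr"][2] - arm_res["standard"][2],
        de_life=arm_res["ffr"][3] - arm_res["standard"][3],
        n_draws=n_draws,
        seed=seed,
        mode=mode,
        param_draws={"treatment_probs": probs, "mace_mt": mace_mt, "or_pci": or_pci, "or_cabg": or_cabg},
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# decision outputs

def icer(delta_cost: float, delta_effect: float):
    """ICER, or a dominance label. Returns 'dominant' (cheaper, more
    effective), 'dominated' (dearer, less effective), 'undefined' at
    delta_effect = 0, else the cost per QALY."""
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("increments must be finite")
    if delta_effect == 0:
        return "undefined"
    if delta_cost < 0 and delta_effect > 0:
        return "dominant"
    if delta_cost > 0 and delta_effect < 0:
        return "dominated"
    return float(delta_cost / delta_effect)


def ceac(dc: np.ndarray, de: np.ndarray, wtp_grid: np.ndarray) -> np.ndarray:
    """Probability of positive net monetary benefit at each willingness to
    pay: fraction of draws with lambda * dE - dC > 0."""
    dc = np.asarray(dc, dtype=float)
    de = np.asarray(de, dtype=float)
    if len(dc) == 0:
        raise ValueError("need at least one draw")
    grid = np.asarray(wtp_grid, dtype=float)
    return np.array([float(np.mean(lam * de - dc > 0)) for lam in grid])


DEFAULT_WTP_GRID = np.arange(0, 50_001, 500)


@dataclass
class CEResult:
    """Mean increments with percentile CIs, ICERs and CEAC per horizon."""

    summary: pd.DataFrame
    icer_trial: object
    icer_life: object
    ceac_table: pd.DataFrame


def summarise_psa(draws: PsaDraws, wtp_grid: np.ndarray = DEFAULT_WTP_GRID) -> CEResult:
    rows = {}
    for name, arr in (
        ("dc_trial", draws.dc_trial),
        ("de_trial", draws.de_trial),
        ("dc_life", draws.dc_life),
        ("de_life", draws.de_life),
    ):
        lo, hi = np.percentile(arr, [2.5, 97.5])
        rows[name] = {"mean": float(arr.mean()), "ci_low": float(lo), "ci_high": float(hi)}
    summary = pd.DataFrame(rows).T
    ceac_table = pd.DataFrame(
        {
            "wtp": wtp_grid,
            "prob_trial": ceac(draws.dc_trial, draws.de_trial, wtp_grid),
            "prob_life": ceac(draws.dc_life, draws.de_life, wtp_grid),
        }
    )
    return CEResult(
        summary=summary,
        icer_trial=icer(float(draws.dc_trial.mean()), float(draws.de_trial.mean())),
        icer_life=icer(float(draws.dc_life.mean()), float(draws.de_life.mean())),
        ceac_table=ceac_table,
    )
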