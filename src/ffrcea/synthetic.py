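"""Seeded synthetic-trial generator.

Emulates an individual-level two-arm randomised trial in recent NSTEMI
(FFR-guided vs standard angiography-guided management) with the statistical
structure the downstream analysis assumes:

* per-arm multinomial treatment decisions (MT / PCI / CABG);
* MACE risk driven by the treatment decision through odds ratios applied to
  a covariate-dependent medical-therapy baseline, with a conditional split
  of MACE into death / MI / stroke / revascularisation;
* correlated EQ-5D utility trajectories at 0, 6 and 12 months whose
  survivor means and arm-level QALY totals are calibrated to configured
  targets, with completely-at-random missingness at the 6- and 12-month
  visits (never at baseline);
* per-category resource use whose expected assembled cost matches the
  configured arm-level category means.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import (
    ARMS,
    DECISIONS,
    EQ5D_MAX,
    EQ5D_MIN,
    MACE_EVENTS,
    ConfigurationError,
    TrialConfig,
    UnitCostTable,
    load_unit_costs,
)
from .decision_model import apply_or

UTILITY_TIMES = (0.0, 0.5, 1.0)
UTILITY_COLS = ("utility_0", "utility_6m", "utility_12m")

RESOURCE_COLUMNS = (
    "wires", "adenosine_vials",
    "guiding_catheters", "guidewires", "balloons", "des_stents", "bms_stents",
    "cabg_performed",
    "tirofiban_gbp", "bivalirudin_gbp", "clopidogrel_months",
    "cathlab_hours", "ccu_days", "itu_days", "ward_days",
    "echos", "oct", "ivus", "xrays",
    "rehospitalisations", "revascularisations", "mi_events", "strokes",
    "severe_bleeds",
)


# ---------------------------------------------------------------------------
# censored-normal helpers: utilities are drawn latent-normal then clipped to
# the EQ-5D index range, so the latent mean must be solved from the target
# post-clipping mean.

def _censored_normal_mean(mu: float, sd: float, a: float = EQ5D_MIN, b: float = EQ5D_MAX) -> float:
    alpha = (a - mu) / sd
    beta = (b - mu) / sd
    return (
        a * stats.norm.cdf(alpha)
        + b * stats.norm.sf(beta)
        + mu * (stats.norm.cdf(beta) - stats.norm.cdf(alpha))
        - sd * (stats.norm.pdf(beta) - stats.norm.pdf(alpha))
    )


def _latent_mean_for_target(target: float, sd: float) -> float:
    if not (EQ5D_MIN < target < EQ5D_MAX):
        raise ConfigurationError(f"utility target must lie strictly inside the EQ-5D range, got {target}")
    return optimize.brentq(
        lambda mu: _censored_normal_mean(mu, sd) - target,
        EQ5D_MIN - 6 * sd,
        EQ5D_MAX + 6 * sd,
        xtol=1e-12,
    )


# ---------------------------------------------------------------------------
# calibration of the arm-level QALY totals

def _trapezoid(u0: float, u6: float, u12: float) -> float:
    return 0.25 * u0 + 0.5 * u6 + 0.25 * u12


def _expected_death_qaly(u0: float, u6: float, lo: float, hi: float) -> float:
    """E[QALY | death at t ~ U(lo, hi)] for the piecewise-linear trajectory
    that interpolates to 0 at the death time."""
    t = np.linspace(lo, hi, 2001)
    early = t <= 0.5
    q = np.where(
        early,
        u0 * t / 2.0,
        (u0 + u6) / 4.0 + u6 * np.clip(t - 0.5, 0.0, None) / 2.0,
    )
    return float(np.trapezoid(q, t) / (hi - lo))


def expected_mace_risks(config: TrialConfig) -> np.ndarray:
    """Population-average MACE risks by decision (MT, PCI, CABG)."""
    base = config.mace_baseline
    return np.array([base, apply_or(base, config.mace_or_pci), apply_or(base, config.mace_or_cabg)])


def expected_mace_probability(config: TrialConfig, arm: str) -> float:
    return float(np.dot(config.treatment_probs[arm], expected_mace_risks(config)))


def calibrated_utility_means(config: TrialConfig) -> dict[str, np.ndarray]:
    """Survivor utility means per arm after the QALY-total calibration offset.

    The configured trapezoid of survivor means and the configured QALY total
    are mutually inconsistent once index-year deaths exist, so an additive
    offset on the configured `qaly_adjust_times` of each arm is solved such
    that the expected arm QALY (survivors + deaths) hits the target.
    """
    lo, hi = config.death_time_range
    out = {}
    for arm in ARMS:
        u0, u6, u12 = config.utility_targets[arm]
        d = expected_mace_probability(config, arm) * config.mace_event_split[0]
        adjust = config.qaly_adjust_times.get(arm, ())
        a6 = 1.0 if 0.5 in adjust else 0.0
        a12 = 1.0 if 1.0 in adjust else 0.0

        def expected_qaly(delta: float) -> float:
            v6 = u6 + a6 * delta
            v12 = u12 + a12 * delta
            return (1 - d) * _trapezoid(u0, v6, v12) + d * _expected_death_qaly(u0, v6, lo, hi)

        if not adjust:
            delta = 0.0
        else:
            delta = optimize.brentq(
                lambda x: expected_qaly(x) - config.qaly_targets[arm], -0.5, 0.5, xtol=1e-12
            )
        out[arm] = np.array([u0, u6 + a6 * delta, u12 + a12 * delta])
    return out


# ---------------------------------------------------------------------------
# resource-quantity calibration

def calibrate_quantity_means(
    category_cost_targets: dict[str, float],
    unit_costs: UnitCostTable,
    weights: dict[str, dict[str, float]],
) -> dict[str, dict[str, float]]:
    """Invert the costing step: per-category mean quantities such that
    quantity x unit cost recovers the target mean cost, allocated across the
    category's items by the configured cost-share weights."""
    out: dict[str, dict[str, float]] = {}
    for cat, target in category_cost_targets.items():
        if cat not in weights:
            continue
        w = weights[cat]
        total_w = sum(w.values())
        out[cat] = {}
        for item, share in w.items():
            unit = unit_costs.mean(item)
            budget = target * share / total_w
            if unit == 0:
                if budget > 0:
                    raise ConfigurationError(
                        f"unit cost for {item!r} is zero but category {cat!r} has a nonzero target"
                    )
                out[cat][item] = 0.0
            else:
                out[cat][item] = budget / unit
    return out


# ---------------------------------------------------------------------------
# individual simulation steps

def assign_treatment(config: TrialConfig, arm: str, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Multinomial treatment-decision draw from the arm's (MT, PCI, CABG) vector."""
    probs = np.asarray(config.treatment_probs[arm], dtype=float)
    idx = rng.choice(3, size=size, p=probs)
    return np.array(DECISIONS, dtype=object)[idx]


def _mace_eta(config: TrialConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Covariate part of the MT log-odds (no intercept)."""
    eff = config.mace_covariate_effects
    return (
        eff.utility * covariates["utility_0"].to_numpy(dtype=float)
        + eff.age * (covariates["age"].to_numpy(dtype=float) - config.covariates.age_mean)
        + eff.sex * covariates["sex"].to_numpy(dtype=float)
        + eff.copd * covariates["copd"].to_numpy(dtype=float)
    )


def _calibrate_mace_intercept(config: TrialConfig, eta: np.ndarray) -> float:
    """Intercept such that the population-average MT risk equals the baseline."""
    target = config.mace_baseline

    def f(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta))))) - target

    return optimize.brentq(f, -20.0, 20.0, xtol=1e-12)


def simulate_mace(
    decisions: np.ndarray,
    covariates: pd.DataFrame,
    config: TrialConfig,
    rng: np.random.Generator,
    intercept: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw MACE indicators and, for events, the conditional event type.

    The patient's MT log-odds is shifted by log OR for PCI/CABG decisions,
    mirroring how the analysis model applies odds ratios to baseline odds.
    """
    for name, or_ in (("mace_or_pci", config.mace_or_pci), ("mace_or_cabg", config.mace_or_cabg)):
        if or_ <= 0:
            raise ConfigurationError(f"{name} must be > 0, got {or_}")
    eta = _mace_eta(config, covariates)
    if intercept is None:
        intercept = _calibrate_mace_intercept(config, eta)
    shift = np.zeros(len(decisions))
    shift[decisions == "PCI"] = np.log(config.mace_or_pci)
    shift[decisions == "CABG"] = np.log(config.mace_or_cabg)
    risk = 1.0 / (1.0 + np.exp(-(intercept + eta + shift)))
    mace = rng.random(len(decisions)) < risk
    events = np.full(len(decisions), "", dtype=object)
    n_mace = int(mace.sum())
    if n_mace:
        idx = rng.choice(4, size=n_mace, p=np.asarray(config.mace_event_split))
        events[mace] = np.array(MACE_EVENTS, dtype=object)[idx]
    return mace, events


def simulate_utilities(
    config: TrialConfig, arm: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Correlated survivor EQ-5D draws at 0/6/12 months, clipped to the index
    range, with latent means inverted so post-clipping means hit the
    (QALY-calibrated) targets."""
    targets = calibrated_utility_means(config)[arm]
    sd = config.utility_sd
    mus = np.array([_latent_mean_for_target(t, sd) for t in targets])
    rho = config.utility_corr
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ chol.T
    return np.clip(mus + sd * z, EQ5D_MIN, EQ5D_MAX)


def apply_death_zeros(utilities: np.ndarray, death_time: np.ndarray) -> np.ndarray:
    """Post-death utilities are structurally 0 (not missing)."""
    out = utilities.copy()
    for j, t in enumerate(UTILITY_TIMES[1:], start=1):
        dead = ~np.isnan(death_time) & (death_time <= t)
        out[dead, j] = 0.0
    return out


def apply_missingness(
    utilities: np.ndarray,
    death_time: np.ndarray,
    config: TrialConfig,
    rng: np.random.Generator,
    covariates: Optional[pd.DataFrame] = None,
) -> np.ndarray:
    """Mask 6/12-month values at the configured rates. Baseline is never
    masked; post-death structural zeros are never masked either."""
    out = utilities.copy()
    for j, (t, rate) in enumerate(zip(UTILITY_TIMES[1:], config.missingness_rates), start=1):
        if rate == 0:
            continue
        alive = np.isnan(death_time) | (death_time > t)
        if config.missingness_mode == "mcar" or covariates is None:
            p = np.full(len(out), rate)
        else:
            x = covariates[config.mar_covariate].to_numpy(dtype=float)
            xa = x[alive]

            def marginal(b0: float) -> float:
                return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + config.mar_log_odds * xa))))) - rate

            b0 = optimize.brentq(marginal, -20.0, 20.0)
            p = 1.0 / (1.0 + np.exp(-(b0 + config.mar_log_odds * x)))
        mask = alive & (rng.random(len(out)) < p)
        out[mask, j] = np.nan
    return out


# ---------------------------------------------------------------------------
# the generator

def _draw_covariates(config: TrialConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cc = config.covariates
    a, b = (cc.age_bounds[0] - cc.age_mean) / cc.age_sd, (cc.age_bounds[1] - cc.age_mean) / cc.age_sd
    age = stats.truncnorm.rvs(a, b, loc=cc.age_mean, scale=cc.age_sd, size=n, random_state=rng)
    return pd.DataFrame(
        {
            "age": age,
            "sex": (rng.random(n) < cc.p_male).astype(int),
            "smoker": (rng.random(n) < cc.p_smoker).astype(int),
            "prior_pci": (rng.random(n) < cc.p_prior_pci).astype(int),
            "copd": (rng.random(n) < cc.p_copd).astype(int),
        }
    )


def _expected_mace_event_cost(
    config: TrialConfig, unit_costs: UnitCostTable, arm: str
) -> float:
    """Expected per-patient index-year event cost driven by MACE itself."""
    split = config.mace_event_split  # death, mi, stroke, revascularisation
    per_event = (
        split[1] * unit_costs.mean("mi_event")
        + split[2] * unit_costs.mean("stroke_index_year")
        + split[3] * unit_costs.mean("revascularisation")
    )
    return expected_mace_probability(config, arm) * per_event


def _generate_resources(
    config: TrialConfig,
    unit_costs: UnitCostTable,
    arm: str,
    decisions: np.ndarray,
    events: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(decisions)
    targets = config.category_cost_targets[arm]
    qmeans = calibrate_quantity_means(targets, unit_costs, config.category_item_weights)
    res = {col: np.zeros(n) for col in RESOURCE_COLUMNS}

    # pressure wire: every FFR patient is measured (>= 1 wire); the standard
    # arm carries one protocol-driven wire that the costing step strips.
    if arm == "ffr":
        res["wires"] = 1.0 + rng.poisson(config.wires_per_patient - 1.0, n).astype(float)
    else:
        res["wires"] = np.ones(n)
    res["adenosine_vials"] = rng.poisson(config.adenosine_vials_mean, n).astype(float)

    # PCI materials, conditional on a PCI decision
    p_pci = config.treatment_probs[arm][1]
    is_pci = decisions == "PCI"
    item_col = {
        "guiding_catheter": "guiding_catheters",
        "guidewire": "guidewires",
        "balloon": "balloons",
        "des_stent": "des_stents",
        "bms_stent": "bms_stents",
    }
    for item, col in item_col.items():
        mean_cond = qmeans["pci"][item] / p_pci if p_pci > 0 else 0.0
        draws = rng.poisson(mean_cond, int(is_pci.sum())).astype(float)
        res[col][is_pci] = draws

    res["cabg_performed"] = (decisions == "CABG").astype(float)

    # medications: GP IIb/IIIa inhibitor and bivalirudin as per-patient GBP
    # averages among treated patients; clopidogrel as months of therapy
    q_tiro = min(qmeans["medications"]["tirofiban"], 1.0)
    q_biva = min(qmeans["medications"]["bivalirudin"], 1.0)
    res["tirofiban_gbp"] = (rng.random(n) < q_tiro) * unit_costs.mean("tirofiban")
    res["bivalirudin_gbp"] = (rng.random(n) < q_biva) * unit_costs.mean("bivalirudin")
    res["clopidogrel_months"] = rng.poisson(qmeans["medications"]["clopidogrel_month"], n).astype(float)

    # catheterisation-laboratory hours
    mean_h = targets["cath_lab"] / unit_costs.mean("cathlab_hour")
    shape = config.cathlab_gamma_shape
    res["cathlab_hours"] = rng.gamma(shape, mean_h / shape, n)

    # length of stay (exponential day counts for a long right tail)
    for item, col in (("ccu_day", "ccu_days"), ("itu_day", "itu_days"), ("ward_day", "ward_days")):
        res[col] = rng.gamma(1.0, qmeans["length_of_stay"][item], n)

    # other in-hospital procedures
    for item, col in (("echo", "echos"), ("xray", "xrays"), ("oct", "oct"), ("ivus", "ivus")):
        res[col] = rng.poisson(qmeans["other_procedures"][item], n).astype(float)

    # index-year events: MACE-driven revascularisation / MI / stroke plus a
    # background budget of rehospitalisations and severe bleeds calibrated so
    # the category mean hits its target
    res["revascularisations"] = (events == "revascularisation").astype(float)
    res["mi_events"] = (events == "mi").astype(float)
    res["strokes"] = (events == "stroke").astype(float)
    budget = targets["events"] - _expected_mace_event_cost(config, unit_costs, arm)
    if budget < 0:
        raise ConfigurationError(
            f"events cost target for arm {arm!r} ({targets['events']}) is below the "
            "expected MACE-driven event cost; reduce MACE rates or raise the target"
        )
    bw = config.background_event_weights
    total_w = sum(bw.values())
    for item, col in (("rehospitalisation", "rehospitalisations"), ("severe_bleed", "severe_bleeds")):
        share = bw.get(item, 0.0) / total_w
        res[col] = rng.poisson(share * budget / unit_costs.mean(item), n).astype(float)
    return pd.DataFrame(res)


def generate_trial(
    config: TrialConfig,
    unit_costs: Optional[UnitCostTable] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Generate the full patient table: one row per patient, both arms.

    Deterministic given the configuration (``config.seed`` unless *seed*
    overrides it). Missing utilities are NaN; ``death_time`` is NaN for
    survivors of the index year.
    """
    if unit_costs is None:
        unit_costs = load_unit_costs()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_per_arm

    # phase 1: covariates and survivor utility draws per arm
    frames = {}
    for arm in ARMS:
        cov = _draw_covariates(config, n, rng)
        utils = simulate_utilities(config, arm, n, rng)
        cov["utility_0"] = utils[:, 0]
        frames[arm] = (cov, utils)

    # phase 2: MACE intercept calibrated on the pooled population so that the
    # marginal medical-therapy risk equals the configured baseline
    pooled = pd.concat([frames[arm][0] for arm in ARMS], ignore_index=True)
    intercept = _calibrate_mace_intercept(config, _mace_eta(config, pooled))

    # phase 3: decisions, MACE, deaths, missingness, resources
    lo, hi = config.death_time_range
    out = []
    for arm in ARMS:
        cov, utils = frames[arm]
        decisions = assign_treatment(config, arm, rng, size=n)
        mace, events = simulate_mace(decisions, cov, config, rng, intercept=intercept)
        death_time = np.full(n, np.nan)
        deaths = events == "death"
        death_time[deaths] = rng.uniform(lo, hi, int(deaths.sum()))
        utils = apply_death_zeros(utils, death_time)
        utils = apply_missingness(utils, death_time, config, rng, covariates=cov)
        resources = _generate_resources(config, unit_costs, arm, decisions, events, rng)

        df = cov.drop(columns=["utility_0"]).copy()
        df.insert(0, "arm", arm)
        df["decision"] = decisions
        df["mace"] = mace
        df["mace_event"] = events
        df["death_time"] = death_time
        for j, col in enumerate(UTILITY_COLS):
            df[col] = utils[:, j]
        out.append(pd.concat([df, resources], axis=1))

    table = pd.concat(out, ignore_index=True)
    table.insert(0, "id", np.arange(len(table)))
    return table
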