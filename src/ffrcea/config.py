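"""Configuration schemas and bundled default parameter sets.

Three YAML files ship with the package:

* ``trial_config.yaml`` -- calibration targets for the synthetic-trial
  generator (arm-level treatment-decision probabilities, MACE parameters,
  EQ-5D utility and QALY targets, per-category mean cost targets,
  missingness rates).
* ``unit_costs.yaml`` -- the unit-cost table in 2014 GBP (equipment,
  procedures, hospitalisation, event and disease-related costs).
* ``model_params.yaml`` -- decision-model point values and the mean/SE
  pairs the probabilistic sensitivity analysis calibrates distributions to.
"""

from __future__ import annotations

from importlib import resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

EQ5D_MIN = -0.594
EQ5D_MAX = 1.0

ARMS = ("standard", "ffr")
DECISIONS = ("MT", "PCI", "CABG")
MACE_EVENTS = ("death", "mi", "stroke", "revascularisation")

COST_CATEGORIES = (
    "pressure_wire",
    "pci",
    "cabg",
    "medications",
    "cath_lab",
    "length_of_stay",
    "other_procedures",
    "events",
)


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its schema."""


def _check_prob_vector(name: str, vec: tuple[float, ...]) -> None:
    if any(p < 0 or p > 1 for p in vec):
        raise ConfigurationError(f"{name}: probabilities must lie in [0, 1], got {vec}")
    if abs(sum(vec) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities must sum to 1, got sum {sum(vec)!r}")


class CovariateConfig(BaseModel):
    """Baseline covariate distributions (prevalences / truncated normal age)."""

    model_config = ConfigDict(extra="forbid")

    age_mean: float = 62.0
    age_sd: float = Field(11.0, gt=0)
    age_bounds: tuple[float, float] = (30.0, 95.0)
    p_male: float = Field(0.74, ge=0, le=1)
    p_smoker: float = Field(0.30, ge=0, le=1)
    p_prior_pci: float = Field(0.12, ge=0, le=1)
    p_copd: float = Field(0.11, ge=0, le=1)


class MaceCovariateEffects(BaseModel):
    """Log-odds effects of baseline covariates on MACE (age centred at its mean)."""

    model_config = ConfigDict(extra="forbid")

    utility: float = -0.5
    age: float = 0.02
    sex: float = 0.0
    copd: float = 0.5


class TrialConfig(BaseModel):
    """Calibration targets and knobs for the synthetic-trial generator."""

    model_config = ConfigDict(extra="forbid")

    n_per_arm: int = Field(176, ge=2)
    seed: int = 20140101

    # multinomial treatment-decision probabilities (MT, PCI, CABG) per arm
    treatment_probs: dict[str, tuple[float, float, float]]
    treatment_prob_ses: dict[str, tuple[float, float, float]]

    mace_baseline: float = Field(0.09, gt=0, lt=1)
    mace_or_pci: float = Field(1.01, gt=0)
    mace_or_cabg: float = Field(3.80, gt=0)
    mace_covariate_effects: MaceCovariateEffects = MaceCovariateEffects()
    # conditional split of MACE into (death, MI, stroke, revascularisation)
    mace_event_split: tuple[float, float, float, float] = (0.1, 0.3, 0.1, 0.5)
    death_time_range: tuple[float, float] = (0.0, 1.0)

    covariates: CovariateConfig = CovariateConfig()

    # EQ-5D means at 0 / 6 / 12 months among survivors, per arm
    utility_targets: dict[str, tuple[float, float, float]]
    utility_sd: float = Field(0.2, gt=0)
    utility_corr: float = Field(0.5, ge=0, lt=1)
    # trial-period per-arm mean QALY totals the generator calibrates to
    qaly_targets: dict[str, float]
    # which time points (years) absorb the QALY calibration offset, per arm
    qaly_adjust_times: dict[str, tuple[float, ...]] = {
        "ffr": (0.5,),
        "standard": (0.5, 1.0),
    }

    missingness_rates: tuple[float, float] = (0.17, 0.24)
    missingness_mode: Literal["mcar", "mar"] = "mcar"
    mar_covariate: str = "smoker"
    mar_log_odds: float = 1.0

    # per-arm mean cost targets (GBP) for the 8 reporting categories
    category_cost_targets: dict[str, dict[str, float]]
    # within-category cost-share weights used to allocate quantities to items
    category_item_weights: dict[str, dict[str, float]]
    # split of the background (non-MACE-driven) events budget
    background_event_weights: dict[str, float] = {
        "rehospitalisation": 0.9,
        "severe_bleed": 0.1,
    }

    wires_per_patient: float = Field(1.03, ge=1)
    adenosine_vials_mean: float = Field(0.0, ge=0)
    cathlab_gamma_shape: float = Field(2.0, gt=0)

    @field_validator("missingness_rates")
    @classmethod
    def _rates_valid(cls, v):
        if any(r < 0 or r > 1 for r in v):
            raise ConfigurationError(f"missingness_rates must lie in [0, 1], got {v}")
        return v

    @field_validator("mace_event_split")
    @classmethod
    def _split_valid(cls, v):
        _check_prob_vector("mace_event_split", v)
        return v

    @model_validator(mode="after")
    def _validate(self):
        for arm in ARMS:
            if arm not in self.treatment_probs:
                raise ConfigurationError(f"treatment_probs missing arm {arm!r}")
            _check_prob_vector(f"treatment_probs[{arm}]", self.treatment_probs[arm])
            if arm not in self.utility_targets:
                raise ConfigurationError(f"utility_targets missing arm {arm!r}")
            if arm not in self.qaly_targets:
                raise ConfigurationError(f"qaly_targets missing arm {arm!r}")
            if arm not in self.category_cost_targets:
                raise ConfigurationError(f"category_cost_targets missing arm {arm!r}")
            for cat, target in self.category_cost_targets[arm].items():
                if cat not in COST_CATEGORIES:
                    raise ConfigurationError(f"unknown cost category {cat!r} for arm {arm!r}")
                if target < 0:
                    raise ConfigurationError(
                        f"category_cost_targets[{arm}][{cat}] must be >= 0, got {target}"
                    )
            for u in self.utility_targets[arm]:
                if not (EQ5D_MIN <= u <= EQ5D_MAX):
                    raise ConfigurationError(
                        f"utility_targets[{arm}] outside [{EQ5D_MIN}, {EQ5D_MAX}]: {u}"
                    )
        lo, hi = self.death_time_range
        if not (0 <= lo < hi <= 1):
            raise ConfigurationError(f"death_time_range must satisfy 0 <= lo < hi <= 1, got {(lo, hi)}")
        return self


class UnitCost(BaseModel):
    """One unit-cost entry: mean in 2014 GBP, optional SE, PSA distribution kind."""

    model_config = ConfigDict(extra="forbid")

    mean: float = Field(ge=0)
    se: Optional[float] = Field(None, ge=0)
    dist: Literal["fixed", "gamma"] = "fixed"


class UnitCostTable(BaseModel):
    """Mapping item name -> unit cost. SE absent means the item is fixed in PSA."""

    model_config = ConfigDict(extra="forbid")

    items: dict[str, UnitCost]

    def mean(self, item: str) -> float:
        if item not in self.items:
            raise KeyError(f"unknown resource item {item!r} in unit-cost table")
        return self.items[item].mean

    def __contains__(self, item: str) -> bool:
        return item in self.items


class UtilitySchedule(BaseModel):
    """Age -> utility mapping for the lifetime extension: linear decline."""

    model_config = ConfigDict(extra="forbid")

    base: float = 0.82
    base_age: float = 63.0
    slope_per_year: float = 0.003

    def __call__(self, age):
        import numpy as np

        return np.clip(self.base - self.slope_per_year * (age - self.base_age), 0.0, 1.0)


class ParamWithSE(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mean: float
    se: float = Field(0.0, ge=0)


class OrParam(BaseModel):
    """Odds ratio with its printed 95% CI (drives lognormal calibration)."""

    model_config = ConfigDict(extra="forbid")

    mean: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)


class DecisionModelParams(BaseModel):
    """Every decision-tree and lifetime-extension input."""

    model_config = ConfigDict(extra="forbid")

    treatment_probs: dict[str, tuple[float, float, float]]
    treatment_prob_ses: dict[str, tuple[float, float, float]]
    mace_mt: ParamWithSE
    or_pci: OrParam
    or_cabg: OrParam
    # GBP per (decision, MACE-status) cell of the tree
    branch_costs: dict[str, ParamWithSE]
    # trial-period QALY per arm (tree structure not imposed on QALYs)
    branch_qalys: dict[str, ParamWithSE]
    wire_cost_ffr: ParamWithSE
    life_expectancy_mace: ParamWithSE
    life_expectancy_no_mace: ParamWithSE
    swap_life_expectancy: bool = False
    annual_cost_post_year1: ParamWithSE
    mace_utility_decrement: ParamWithSE
    utility_schedule: UtilitySchedule = UtilitySchedule()
    discount_rate: float = Field(0.035, ge=0)
    starting_age: float = 62.0

    @model_validator(mode="after")
    def _validate(self):
        for arm in ARMS:
            if arm not in self.treatment_probs:
                raise ConfigurationError(f"treatment_probs missing arm {arm!r}")
            _check_prob_vector(f"treatment_probs[{arm}]", self.treatment_probs[arm])
            if arm not in self.branch_qalys:
                raise ConfigurationError(f"branch_qalys missing arm {arm!r}")
        for dec in DECISIONS:
            for status in ("mace", "no_mace"):
                cell = f"{dec}_{status}"
                if cell not in self.branch_costs:
                    raise ConfigurationError(f"branch_costs missing cell {cell!r}")
        if self.life_expectancy_mace.mean < 0 or self.life_expectancy_no_mace.mean < 0:
            raise ConfigurationError("life expectancies must be >= 0")
        if not (-1.0 <= self.mace_utility_decrement.mean <= 0.0):
            raise ConfigurationError("mace_utility_decrement mean must lie in [-1, 0]")
        return self

    def life_expectancies(self) -> tuple[float, float]:
        """(MACE, no-MACE) additional years, honouring the swap flag."""
        le_m = self.life_expectancy_mace.mean
        le_n = self.life_expectancy_no_mace.mean
        return (le_n, le_m) if self.swap_life_expectancy else (le_m, le_n)


def _data_path(name: str):
    return resources.files("ffrcea").joinpath("data").joinpath(name)


def _load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_trial_config(path: Optional[str] = None, **overrides) -> TrialConfig:
    """Load the generator configuration (bundled default when *path* is None)."""
    raw = _load_yaml(path if path is not None else _data_path("trial_config.yaml"))
    raw.update(overrides)
    try:
        return TrialConfig(**raw)
    except ConfigurationError:
        raise
    except ValueError as exc:  # unwrap pydantic's ValidationError
        raise ConfigurationError(str(exc)) from exc


def load_unit_costs(path: Optional[str] = None) -> UnitCostTable:
    raw = _load_yaml(path if path is not None else _data_path("unit_costs.yaml"))
    return UnitCostTable(items=raw)


def load_model_params(path: Optional[str] = None, **overrides) -> DecisionModelParams:
    raw = _load_yaml(path if path is not None else _data_path("model_params.yaml"))
    raw.update(overrides)
    try:
        return DecisionModelParams(**raw)
    except ConfigurationError:
        raise
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
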