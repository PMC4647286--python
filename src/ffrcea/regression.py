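"""Statistical models behind the decision analysis.

Costs and QALYs are modelled with generalised linear models; family and link
are chosen with the modified Park test (variance-power regression) and a
grouped Hosmer-Lemeshow-type calibration test. MACE is modelled with
logistic regression on the treatment decision plus screened baseline
covariates; the PCI/CABG odds ratios are extracted with Wald CIs and the
medical-therapy baseline is obtained by marginal (covariate-standardised)
prediction. Candidate covariates are screened on univariable association
(p < 0.25) and, for binaries, prevalence > 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

FAMILIES = ("gaussian", "poisson", "gamma", "binomial")
LINKS = ("identity", "log", "logit")


@dataclass
class GlmSpec:
    """Model specification: outcome, patsy predictor terms, family and link."""

    outcome: str
    predictors: list[str]
    family: str = "gaussian"
    link: str = "identity"

    def formula(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        return f"{self.outcome} ~ {rhs}"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}; choose from {FAMILIES}")
        if self.link not in LINKS:
            raise ValueError(f"unsupported link {self.link!r}; choose from {LINKS}")


@dataclass
class FittedModel:
    """A fitted GLM plus its specification."""

    spec: GlmSpec
    result: object = field(repr=False)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse

    @property
    def deviance(self) -> float:
        return float(self.result.deviance)

    @property
    def fittedvalues(self) -> pd.Series:
        return self.result.fittedvalues

    @property
    def nobs(self) -> int:
        return int(self.result.nobs)

    @property
    def scale(self) -> float:
        return float(self.result.scale)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.result.predict(table))


def _sm_family(family: str, link: str):
    links = {
        "identity": sm.families.links.Identity(),
        "log": sm.families.links.Log(),
        "logit": sm.families.links.Logit(),
    }
    fams = {
        "gaussian": sm.families.Gaussian,
        "poisson": sm.families.Poisson,
        "gamma": sm.families.Gamma,
        "binomial": sm.families.Binomial,
    }
    return fams[family](links[link])


def fit_glm(table: pd.DataFrame, spec: GlmSpec, maxiter: int = 100, tol: float = 1e-8) -> FittedModel:
    """Iteratively reweighted ML fit; raises on non-convergence or missing data."""
    cols = [spec.outcome]
    used = table  # patsy resolves names itself; check outcome for NaN explicitly
    if used[spec.outcome].isna().any():
        raise ValueError(f"outcome {spec.outcome!r} contains missing values")
    model = smf.glm(spec.formula(), data=table, family=_sm_family(spec.family, spec.link))
    try:
        result = model.fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise RuntimeError(f"GLM fit failed for {spec.formula()!r}: {exc}") from exc
    if not result.converged:
        raise RuntimeError(f"GLM did not converge within {maxiter} iterations: {spec.formula()!r}")
    if not np.all(np.isfinite(result.params)):
        raise RuntimeError(f"non-finite coefficients (separation?) in {spec.formula()!r}")
    return FittedModel(spec=spec, result=result)


def screen_covariates(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    must_include: tuple[str, ...] = (),
    p_threshold: float = 0.25,
    prevalence_threshold: float = 0.10,
) -> list[str]:
    """Retain candidates univariably associated with the outcome at
    p < 0.25; binary covariates additionally need prevalence > 10%.
    Clinically mandated covariates are always kept."""
    y = table[outcome]
    binary_outcome = set(pd.unique(y.dropna())) <= {0, 1, True, False}
    family = "binomial" if binary_outcome else "gaussian"
    link = "logit" if binary_outcome else "identity"
    kept = []
    for cov in candidates:
        if cov in must_include:
            kept.append(cov)
            continue
        x = table[cov].dropna()
        is_binary = set(pd.unique(x)) <= {0, 1, True, False}
        if is_binary:
            prev = float(np.mean(x.astype(float)))
            if min(prev, 1 - prev) <= prevalence_threshold:
                continue
        fitted = fit_glm(table, GlmSpec(outcome, [cov], family=family, link=link))
        p = float(fitted.result.pvalues[fitted.result.pvalues.index != "Intercept"].iloc[0])
        if p < p_threshold:
            kept.append(cov)
    return kept


def modified_park_test(fitted: FittedModel) -> tuple[float, str]:
    """Regress log squared residuals on log fitted values; the slope (the
    variance power) selects the family by a nearest-integer rule:
    0 -> gaussian, 1 -> poisson-like, 2 -> gamma."""
    mu = np.asarray(fitted.fittedvalues, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("modified Park test requires strictly positive fitted values")
    y = np.asarray(fitted.result.model.endog, dtype=float)
    r2 = (y - mu) ** 2
    tol = (1e-10 * max(1.0, float(np.max(np.abs(y))))) ** 2
    if np.all(r2 <= tol):
        raise ValueError("all residuals are (numerically) zero; variance power is undefined")
    keep = r2 > tol
    slope = sm.OLS(np.log(r2[keep]), sm.add_constant(np.log(mu[keep]))).fit().params[1]
    gamma = float(slope)
    family = {0: "gaussian", 1: "poisson", 2: "gamma"}[int(np.clip(round(gamma), 0, 2))]
    return gamma, family


def hosmer_lemeshow(fitted: FittedModel, g: int = 10) -> tuple[float, int, float]:
    """Grouped calibration test: deciles of fitted values, Pearson statistic
    sum (O - E)^2 / V over g groups, df = g - 2."""
    if g < 3:
        raise ValueError("need at least 3 groups")
    mu = np.asarray(fitted.fittedvalues, dtype=float)
    y = np.asarray(fitted.result.model.endog, dtype=float)
    order = np.argsort(mu, kind="stable")
    groups = np.array_split(order, g)
    var_fn = fitted.result.family.variance
    scale = fitted.scale
    stat = 0.0
    for idx in groups:
        if len(idx) == 0:
            continue
        o = float(y[idx].sum())
        e = float(mu[idx].sum())
        v = float(np.sum(var_fn(mu[idx]) * scale))
        if v <= 0:
            raise ValueError("zero variance in a fitted-value group")
        stat += (o - e) ** 2 / v
    df = g - 2
    return float(stat), df, float(stats.chi2.sf(stat, df))


def partial_deviance_test(nested: FittedModel, full: FittedModel) -> float:
    """Chi-squared p-value for the deviance drop of the full over the nested
    model (scaled by the full model's dispersion for non-binomial families)."""
    if nested.spec.outcome != full.spec.outcome or nested.spec.family != full.spec.family:
        raise ValueError("models must share outcome and family")
    if nested.nobs != full.nobs:
        raise ValueError("models must be fitted to the same table")
    nested_cols = set(nested.result.model.exog_names)
    full_cols = set(full.result.model.exog_names)
    if not nested_cols <= full_cols:
        raise ValueError("first model's design columns must be a subset of the second's")
    ddf = len(full.params) - len(nested.params)
    if ddf == 0:
        return 1.0
    phi = 1.0 if full.spec.family == "binomial" else full.scale
    stat = max(nested.deviance - full.deviance, 0.0) / phi
    return float(stats.chi2.sf(stat, ddf))


def fit_logistic(table: pd.DataFrame, spec: GlmSpec) -> tuple[FittedModel, pd.DataFrame]:
    """Binomial/logit fit plus exponentiated coefficients with Wald 95% CIs."""
    spec = GlmSpec(spec.outcome, spec.predictors, family="binomial", link="logit")
    fitted = fit_glm(table, spec)
    params = fitted.params
    bse = fitted.bse
    z = stats.norm.ppf(0.975)
    ors = pd.DataFrame(
        {
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p": fitted.result.pvalues,
        }
    )
    return fitted, ors.drop(index="Intercept", errors="ignore")


def marginal_predict(fitted: FittedModel, table: pd.DataFrame, set_variable: str, level) -> float:
    """Covariate-standardised mean: set *set_variable* to *level* for every
    row, predict on the response scale, and average."""
    training = fitted.result.model.data.frame
    if set_variable in training and not pd.api.types.is_numeric_dtype(training[set_variable]):
        seen = set(training[set_variable].unique())
        if level not in seen:
            raise ValueError(f"level {level!r} of {set_variable!r} was not seen during fitting")
    work = table.copy()
    work[set_variable] = level
    return float(np.mean(fitted.predict(work)))


# canonical model specifications used by the pipeline; the treatment
# decision is coded with medical therapy as the reference level
DECISION_TERM = "C(decision, Treatment('MT'))"
COST_SPEC_PREDICTORS = [f"{DECISION_TERM} * mace", "arm", "utility_0", "age", "sex", "smoker", "prior_pci"]
QALY_SPEC_PREDICTORS = ["arm", "utility_0", "age", "sex", "smoker"]
MACE_SPEC_PREDICTORS = [DECISION_TERM, "utility_0", "age", "sex", "copd"]
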