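"""Trial-period QALYs from EQ-5D trajectories, missingness diagnostics and
multiple imputation by chained equations.

QALYs are the area under the utility curve over the index year (trapezoidal
rule over the 0/6/12-month measurements); a death at time t < 1 interpolates
utility linearly to 0 at the death time and holds it at 0 thereafter.

Missing 6/12-month utilities are imputed by chained Bayesian linear
regressions (each incomplete variable regressed on arm, baseline covariates,
baseline utility and the other follow-up utility; parameter and residual
uncertainty drawn per imputation) and pooled by Rubin's rules.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import EQ5D_MAX, EQ5D_MIN

UTILITY_TIMES = (0.0, 0.5, 1.0)
UTILITY_COLS = ("utility_0", "utility_6m", "utility_12m")


class MissingUtilityError(ValueError):
    """Raised when a QALY is requested from an incomplete trajectory."""


def qaly_auc(values: Sequence[float], death_time: float | None = None) -> float:
    """Trapezoidal QALY over [0, 1] year from utilities at 0, 0.5 and 1.0.

    With a death at ``death_time`` < 1, utility declines linearly from the
    last pre-death measurement to 0 at the death time and stays 0.
    """
    u = np.asarray(values, dtype=float)
    if death_time is None or (isinstance(death_time, float) and np.isnan(death_time)):
        if np.any(np.isnan(u)):
            raise MissingUtilityError(
                "utility trajectory has missing values; impute before computing QALYs"
            )
        return float(np.trapezoid(u, UTILITY_TIMES))
    td = float(death_time)
    if np.isnan(u[0]):
        raise MissingUtilityError("baseline utility must never be missing")
    if td <= 0.5:
        return float(u[0] * td / 2.0)
    if np.isnan(u[1]):
        raise MissingUtilityError("6-month utility missing for a post-6-month death")
    if td >= 1.0:
        if np.any(np.isnan(u)):
            raise MissingUtilityError("utility trajectory has missing values")
        return float(np.trapezoid(u, UTILITY_TIMES))
    return float((u[0] + u[1]) / 4.0 + u[1] * (td - 0.5) / 2.0)


def qaly_table(table: pd.DataFrame) -> pd.Series:
    """Vectorised per-patient QALYs for a completed patient table."""
    u = table[list(UTILITY_COLS)].to_numpy(dtype=float)
    td = table["death_time"].to_numpy(dtype=float) if "death_time" in table else np.full(len(table), np.nan)
    alive = np.isnan(td)
    needed = np.where(alive[:, None], True, np.array(UTILITY_TIMES)[None, :] < np.where(alive, 1.0, td)[:, None])
    if np.any(np.isnan(u) & needed):
        raise MissingUtilityError("utility table has missing values; impute first")
    out = np.trapezoid(u, UTILITY_TIMES, axis=1)
    early = ~alive & (td <= 0.5)
    out[early] = u[early, 0] * td[early] / 2.0
    late = ~alive & (td > 0.5) & (td < 1.0)
    out[late] = (u[late, 0] + u[late, 1]) / 4.0 + u[late, 1] * (td[late] - 0.5) / 2.0
    return pd.Series(out, index=table.index, name="qaly")


def chi2_pvalue(statistic: float, df: int) -> float:
    """Upper-tail p-value from the chi-squared survival function."""
    return float(stats.chi2.sf(statistic, df))


def missingness_test(table: Union[pd.DataFrame, np.ndarray], column: str = "utility_12m"):
    """Pearson chi-squared (no continuity correction) on the 2x2
    arm x missingness table; returns (statistic, df, p)."""
    if isinstance(table, pd.DataFrame):
        missing = table[column].isna()
        ct = pd.crosstab(table["arm"], missing).to_numpy()
    else:
        ct = np.asarray(table, dtype=float)
    if ct.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {ct.shape}")
    if np.any(ct.sum(axis=0) == 0) or np.any(ct.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, dof, _ = stats.chi2_contingency(ct, correction=False)
    return float(stat), int(dof), float(p)


_PREDICTORS = ("age", "sex", "smoker", "prior_pci", "copd", "utility_0")


def _design(table: pd.DataFrame, other_col: str) -> np.ndarray:
    cols = [np.ones(len(table)), (table["arm"] == "ffr").to_numpy(dtype=float)]
    cols += [table[c].to_numpy(dtype=float) for c in _PREDICTORS if c in table.columns]
    cols.append(table[other_col].to_numpy(dtype=float))
    return np.column_stack(cols)


def impute_missing(table: pd.DataFrame, m: int = 20, seed: int = 0, cycles: int = 5) -> list[pd.DataFrame]:
    """Chained-equation multiple imputation of the 6/12-month utilities.

    Each incomplete column is regressed on arm, baseline covariates, baseline
    utility and the other follow-up column; imputations draw the residual
    variance from its scaled inverse-chi-squared posterior, coefficients from
    their normal posterior, and add residual noise. Imputed values are
    truncated to the EQ-5D range. Structural post-death zeros are neither
    treated as observations nor overwritten. Deterministic given *seed*.
    """
    if m < 2:
        raise ValueError("Rubin's rules require m >= 2 imputations")
    td = table["death_time"].to_numpy(dtype=float) if "death_time" in table else np.full(len(table), np.nan)
    info = {}
    for col, t in zip(("utility_6m", "utility_12m"), (0.5, 1.0)):
        alive = np.isnan(td) | (td > t)
        miss = table[col].isna().to_numpy() & alive
        info[col] = (alive, miss)
    if not any(miss.any() for _, miss in info.values()):
        return [table.copy() for _ in range(m)]

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        work = table.copy()
        # initialise missing cells by resampling observed survivor values
        for col, (alive, miss) in info.items():
            obs = work.loc[alive & ~miss, col].to_numpy(dtype=float)
            if len(obs) == 0:
                raise ValueError(f"no observed values to initialise {col!r}")
            work.loc[miss, col] = rng.choice(obs, size=int(miss.sum()))
        for _cycle in range(cycles):
            for col, other in (("utility_6m", "utility_12m"), ("utility_12m", "utility_6m")):
                alive, miss = info[col]
                if not miss.any():
                    continue
                fit_rows = alive & ~miss
                X = _design(work, other)
                y = work[col].to_numpy(dtype=float)
                Xf, yf = X[fit_rows], y[fit_rows]
                beta_hat, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
                resid = yf - Xf @ beta_hat
                dof = len(yf) - Xf.shape[1]
                sigma2 = resid @ resid / rng.chisquare(dof)
                xtx_inv = np.linalg.pinv(Xf.T @ Xf)
                L = np.linalg.cholesky(xtx_inv * sigma2 + 1e-12 * np.eye(len(beta_hat)))
                beta = beta_hat + L @ rng.standard_normal(len(beta_hat))
                draw = X[miss] @ beta + rng.normal(0.0, np.sqrt(sigma2), int(miss.sum()))
                work.loc[miss, col] = np.clip(draw, EQ5D_MIN, EQ5D_MAX)
        out.append(work)
    return out


def pool_rubin(estimates: Sequence[float], variances: Sequence[float]) -> tuple[float, float]:
    """Rubin's rules: pooled mean and its standard error.

    Total variance = within + (1 + 1/m) * between.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin's rules require at least 2 estimates")
    pooled = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return pooled, float(np.sqrt(total))
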