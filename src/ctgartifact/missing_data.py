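"""Multiple imputation of BMI and Rubin's-rules pooling.

Maternal BMI is the single incompletely observed covariate (about 6.3%
missing in the cohort the package emulates).  Imputation is Bayesian
normal linear regression of BMI on configured predictors: for each of m
imputations the residual variance and coefficient vector are drawn from
their posterior under the standard noninformative prior, and missing
values are filled with the linear predictor plus Gaussian noise.
Including the exposure and outcome among the predictors keeps the
imputation model congenial with the analysis model.

Pooling follows Rubin's rules: pooled point = mean of the m estimates;
total variance = mean within-imputation variance + (1 + 1/m) x
between-imputation variance; degrees of freedom by the Barnard-Rubin
small-sample formula when a complete-data df is supplied, else the
classical large-sample Rubin df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .causal import build_design
from .errors import ConfigurationError


@dataclass
class ImputationResult:
    """Rubin-pooled estimate across m imputations (log-OR scale)."""

    m: int
    estimates: np.ndarray
    variances: np.ndarray
    pooled_estimate: float
    within_variance: float
    between_variance: float
    pooled_variance: float
    df: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.pooled_variance))

    def ci(self, conf: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + conf / 2, self.df)
        return (
            self.pooled_estimate - t * self.se,
            self.pooled_estimate + t * self.se,
        )


def impute_bmi(
    cohort: pd.DataFrame,
    predictors: list[str],
    m: int = 20,
    seed: int | None = None,
    column: str = "bmi",
) -> list[pd.DataFrame]:
    """m completed cohorts with missing BMI drawn from its posterior.

    Observed BMI values are never altered; with zero missing values the
    m outputs are identical copies of the input.  Only a single
    incomplete covariate is supported: any missingness among the
    predictors raises.
    """
    if m < 2:
        raise ConfigurationError("m must be >= 2 imputations")
    if column not in cohort.columns:
        raise ConfigurationError(f"column {column!r} not in cohort")
    incomplete_preds = [p for p in predictors if cohort[p].isna().any()]
    if incomplete_preds:
        raise ConfigurationError(
            "only BMI may be incomplete; predictors with missing values: "
            f"{incomplete_preds}"
        )
    miss = cohort[column].isna().to_numpy()
    if not miss.any():
        return [cohort.copy() for _ in range(m)]
    rng = np.random.default_rng(seed)
    X, _ = build_design(cohort, predictors)
    Xobs, yobs = X[~miss], cohort.loc[~miss, column].to_numpy(float)
    Xmis = X[miss]
    n_obs, p = Xobs.shape
    XtX = Xobs.T @ Xobs
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xobs.T @ yobs)
    resid = yobs - Xobs @ beta_hat
    dof = n_obs - p
    s2 = float(resid @ resid) / dof
    chol = np.linalg.cholesky(XtX_inv)
    completed = []
    for _ in range(m):
        sigma2 = dof * s2 / rng.chisquare(dof)
        beta_draw = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
        draws = Xmis @ beta_draw + np.sqrt(sigma2) * rng.standard_normal(Xmis.shape[0])
        out = cohort.copy()
        out.loc[miss, column] = draws
        completed.append(out)
    return completed


def pool_rubin(
    estimates: np.ndarray,
    variances: np.ndarray,
    df_complete: float | None = None,
) -> ImputationResult:
    """Combine m point estimates and variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.shape[0]
    if m < 2:
        raise ConfigurationError("pooling requires m >= 2 estimates")
    if np.any(u <= 0):
        raise ConfigurationError("within-imputation variances must be positive")
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1))
    total = wbar + (1 + 1 / m) * b
    if b == 0:
        df = np.inf
    else:
        r = (1 + 1 / m) * b / wbar
        df_old = (m - 1) * (1 + 1 / r) ** 2
        if df_complete is None:
            df = df_old
        else:
            lam = (1 + 1 / m) * b / total
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return ImputationResult(
        m=m,
        estimates=q,
        variances=u,
        pooled_estimate=qbar,
        within_variance=wbar,
        between_variance=b,
        pooled_variance=total,
        df=float(df),
    )
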