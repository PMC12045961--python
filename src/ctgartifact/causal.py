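"""Doubly robust estimation of the exposure effect on a binary outcome.

The estimator is inverse-probability-weighted regression adjustment
(IPW-RA): a logistic propensity model for the binary exposure yields
stabilized ATE weights, and a weighted logistic outcome regression on
exposure plus covariates yields the adjusted odds ratio.  The estimate
is consistent if either the propensity model or the outcome model is
correctly specified ("doubly robust").  Inference treats the weights as
fixed and uses a robust sandwich variance; a nonparametric bootstrap is
available as a sensitivity mode.

Also here: the shared IRLS logistic engine, standardized-mean-difference
balance diagnostics, likelihood-ratio tests between nested fits, and the
quantile dose–response analysis replacing the binary exposure with
log-quantile dropout bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import EffectEstimate
from .errors import (
    ConfigurationError,
    PositivityError,
    RankDeficiencyError,
    SeparationError,
)

_MAX_ABS_COEF = 40.0  # |log-odds| beyond this flags quasi-complete separation
_IRLS_TOL = 1e-8
_IRLS_MAXITER = 100


@dataclass
class LogisticFit:
    """A fitted (optionally weighted) logistic regression."""

    params: np.ndarray
    cov: np.ndarray
    fitted: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    feature_names: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.params.shape[0]

    def se(self, robust_cov: np.ndarray | None = None) -> np.ndarray:
        cov = self.cov if robust_cov is None else robust_cov
        return np.sqrt(np.diag(cov))


@dataclass
class IPWeights:
    """Inverse-probability-of-exposure weights for the ATE."""

    weights: np.ndarray
    estimand: str = "ATE"
    stabilized: bool = True
    truncation_bounds: tuple[float, float] | None = (1.0, 99.0)


@dataclass
class LRTestResult:
    statistic: float
    df: int
    p: float


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # near-zero R diagonal from QR names the offending (collinear) columns
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.flatnonzero(diag < max(tol, 1e-10))
    if bad.size:
        offending = [names[i] if i < len(names) else f"col{i}" for i in bad]
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {offending}"
        )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``X`` must include the intercept column.  ``weights`` are per-record
    case weights entering the (pseudo-)log-likelihood
    sum_i w_i [y_i log p_i + (1-y_i) log(1-p_i)].  Convergence when the
    max absolute coefficient change drops below 1e-8, up to 100
    iterations.  Diverging coefficients (|beta| > 40 on the log-odds
    scale) raise :class:`SeparationError`; rank-deficient designs raise
    :class:`RankDeficiencyError` naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n, p = X.shape
    names = feature_names or [f"x{i}" for i in range(p)]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    _check_rank(X * np.sqrt(w)[:, None], names)

    beta = np.zeros(p)
    # start intercept at the weighted logit of the mean for faster convergence
    ybar = np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6)
    const_cols = np.flatnonzero(np.all(X == X[0, :], axis=0) & (X[0, :] != 0))
    if const_cols.size:
        beta[const_cols[0]] = np.log(ybar / (1 - ybar)) / X[0, const_cols[0]]

    converged = False
    it = 0
    for it in range(1, _IRLS_MAXITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        s = w * mu * (1 - mu)
        XtWX = (X * s[:, None]).T @ X
        score = X.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular during IRLS (likely separation)"
            ) from exc
        beta_new = beta + step
        if np.max(np.abs(beta_new)) > _MAX_ABS_COEF:
            raise SeparationError(
                "coefficients diverging (quasi-complete separation suspected); "
                f"max |beta| > {_MAX_ABS_COEF}"
            )
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < _IRLS_TOL:
            converged = True
            break

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500))), 1e-12, 1 - 1e-12)
    llf = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
    s = w * mu * (1 - mu)
    XtWX = (X * s[:, None]).T @ X
    cov = np.linalg.inv(XtWX)
    return LogisticFit(
        params=beta,
        cov=cov,
        fitted=mu,
        llf=llf,
        converged=converged,
        n_iter=it,
        feature_names=list(names),
        weights=None if weights is None else w,
    )


def sandwich_cov(fit: LogisticFit, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Robust (HC0) sandwich covariance treating case weights as fixed.

    bread = (X' diag(w·p·(1−p)) X)^{-1};
    meat  = Σ_i w_i² (y_i − p_i)² x_i x_iᵀ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(X.shape[0]) if fit.weights is None else fit.weights
    mu = fit.fitted
    s = w * mu * (1 - mu)
    bread = np.linalg.inv((X * s[:, None]).T @ X)
    resid = w * (y - mu)
    meat = (X * (resid**2)[:, None]).T @ X
    return bread @ meat @ bread


def build_design(
    df: pd.DataFrame, covariates: list[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix from cohort columns.

    Categorical (object/category) columns are expanded to drop-first
    indicator columns; boolean columns become 0/1.  Returns the matrix
    and its column names, with the intercept first.
    """
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ConfigurationError(f"covariates not in cohort table: {missing}")
    parts, names = [], []
    if add_intercept:
        parts.append(np.ones((len(df), 1)))
        names.append("intercept")
    for col in covariates:
        s = df[col]
        if s.isna().any():
            raise ConfigurationError(
                f"covariate {col!r} has missing values; impute or drop first"
            )
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True)
            parts.append(dummies.to_numpy(float))
            names.extend(dummies.columns.tolist())
        else:
            parts.append(s.to_numpy(float)[:, None])
            names.append(col)
    return np.hstack(parts), names


def estimate_propensity(
    cohort: pd.DataFrame,
    covariates: list[str],
    exposure_col: str = "exposure_high",
) -> LogisticFit:
    """Logistic propensity model for exposure given confounders.

    The fitted probabilities are the propensity scores e(x) used to form
    inverse-probability weights.
    """
    X, names = build_design(cohort, covariates)
    y = cohort[exposure_col].to_numpy(float)
    return fit_logistic(X, y, feature_names=names)


def ipw_weights(
    scores: np.ndarray,
    exposure: np.ndarray,
    stabilized: bool = True,
    truncate_pct: tuple[float, float] | None = (1.0, 99.0),
) -> IPWeights:
    """ATE weights: 1/e for the exposed, 1/(1−e) for the unexposed.

    Stabilization multiplies by the marginal arm probability, which
    keeps the weighted pseudo-population the size of the sample;
    truncation clips the weights at the given percentiles of their own
    distribution, a standard guard against extreme scores.
    """
    scores = np.asarray(scores, dtype=float)
    a = np.asarray(exposure, dtype=bool)
    if np.any((scores <= 0) | (scores >= 1)):
        raise PositivityError("propensity score of exactly 0 or 1 encountered")
    w = np.where(a, 1.0 / scores, 1.0 / (1.0 - scores))
    if stabilized:
        pa = a.mean()
        w = np.where(a, pa, 1.0 - pa) * w
    if truncate_pct is not None:
        lo, hi = np.percentile(w, truncate_pct)
        w = np.clip(w, lo, hi)
    return IPWeights(
        weights=w,
        stabilized=stabilized,
        truncation_bounds=truncate_pct,
    )


def balance_table(
    cohort: pd.DataFrame,
    covariates: list[str],
    weights: IPWeights | np.ndarray,
    exposure_col: str = "exposure_high",
) -> pd.DataFrame:
    """Standardized mean differences before and after weighting.

    SMD = (mean difference between arms) / pooled *unweighted* standard
    deviation, so the denominator is the same before and after weighting
    and the weighted SMD reflects only the shift in means.  Categorical
    covariates are expanded to indicators.  A constant covariate has
    SMD 0.
    """
    w = weights.weights if isinstance(weights, IPWeights) else np.asarray(weights)
    a = cohort[exposure_col].to_numpy(bool)
    X, names = build_design(cohort, covariates, add_intercept=False)
    rows = []
    for j, name in enumerate(names):
        x = X[:, j]
        sd = np.sqrt((np.var(x[a], ddof=1) + np.var(x[~a], ddof=1)) / 2)
        mean_diff = x[a].mean() - x[~a].mean()
        wmean1 = np.average(x[a], weights=w[a])
        wmean0 = np.average(x[~a], weights=w[~a])
        if sd == 0:
            smd_u = 0.0 if mean_diff == 0 else np.nan
            smd_w = 0.0 if wmean1 == wmean0 else np.nan
        else:
            smd_u = mean_diff / sd
            smd_w = (wmean1 - wmean0) / sd
        rows.append(
            dict(covariate=name, smd_unweighted=smd_u, smd_weighted=smd_w)
        )
    return pd.DataFrame(rows)


def _wald_effect(
    beta: float, se: float, method: str, n_exposed: int, n_unexposed: int,
    conf: float = 0.95, label: str = ""
) -> EffectEstimate:
    z = stats.norm.ppf(0.5 + conf / 2)
    return EffectEstimate(
        or_value=float(np.exp(beta)),
        ci_lo=float(np.exp(beta - z * se)),
        ci_hi=float(np.exp(beta + z * se)),
        p=float(2 * stats.norm.sf(abs(beta) / se)),
        method=method,
        n_exposed=n_exposed,
        n_unexposed=n_unexposed,
        label=label,
    )


def doubly_robust_effect(
    cohort: pd.DataFrame,
    covariates: list[str],
    weights: IPWeights | np.ndarray | None,
    exposure_col: str = "exposure_high",
    outcome_col: str = "asphyxia",
    bootstrap: int = 0,
    seed: int | None = None,
) -> EffectEstimate:
    """IPW-weighted, covariate-adjusted logistic odds ratio (aOR).

    Fits a weighted logistic regression of the outcome on exposure plus
    ``covariates`` and exponentiates the exposure coefficient.  CI and
    p come from the sandwich variance treating weights as fixed; with
    ``bootstrap`` > 0 the CI is replaced by the percentile bootstrap
    over resampled cohorts (weights re-derived are NOT re-estimated —
    pass a propensity-covariate list via the pipeline for that).

    With ``weights=None`` (equal weights) and an empty covariate list
    this reduces exactly to the crude 2x2 odds ratio.
    """
    a = cohort[exposure_col].to_numpy(float)
    y = cohort[outcome_col].to_numpy(float)
    if a.min() == a.max():
        raise ConfigurationError("cohort has a single exposure arm")
    Xc, names = build_design(cohort, covariates)
    X = np.hstack([Xc[:, :1], a[:, None], Xc[:, 1:]])
    names = [names[0], "exposure"] + names[1:]
    w = None
    if weights is not None:
        w = weights.weights if isinstance(weights, IPWeights) else np.asarray(weights)
    fit = fit_logistic(X, y, weights=w, feature_names=names)
    rcov = sandwich_cov(fit, X, y)
    beta, se = fit.params[1], float(np.sqrt(rcov[1, 1]))
    method = "doubly_robust" if weights is not None else (
        "adjusted" if covariates else "unadjusted"
    )
    est = _wald_effect(
        beta, se, method, int(a.sum()), int((1 - a).sum())
    )
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(cohort)
        reps = []
        for _ in range(bootstrap):
            idx = rng.integers(0, n, n)
            try:
                f = fit_logistic(
                    X[idx], y[idx],
                    weights=None if w is None else w[idx],
                    feature_names=names,
                )
                reps.append(f.params[1])
            except (SeparationError, RankDeficiencyError):
                continue
        if len(reps) >= max(50, bootstrap // 2):
            lo, hi = np.percentile(reps, [2.5, 97.5])
            est.ci_lo, est.ci_hi = float(np.exp(lo)), float(np.exp(hi))
            est.method += "_bootstrap"
    return est


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> LRTestResult:
    """LR test between nested fits on the same records and weights.

    statistic = 2·(llf_full − llf_reduced), df = parameter difference.
    """
    if not set(reduced.feature_names) <= set(full.feature_names):
        raise ValueError(
            "reduced model is not nested in full model (feature sets differ)"
        )
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than reduced")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTestResult(statistic=stat, df=df, p=p)


def quantile_dose_response(
    cohort: pd.DataFrame,
    bin_col: str,
    covariates: list[str],
    weights: IPWeights | np.ndarray | None = None,
    outcome_col: str = "asphyxia",
) -> tuple[list[EffectEstimate], LRTestResult]:
    """Per-bin aORs for log-quantile dropout bins vs the lowest bin.

    Replaces the binary exposure with k−1 indicator columns (reference =
    bin 0, the lowest dropout) in the weighted adjusted outcome model,
    and jointly tests the k−1 indicators with a likelihood-ratio test
    against the covariate-only model.
    """
    bins = cohort[bin_col].to_numpy(int)
    k = bins.max() + 1
    counts = np.bincount(bins, minlength=k)
    if np.any(counts == 0):
        raise ConfigurationError(f"empty dose-response bin: {np.flatnonzero(counts == 0).tolist()}")
    y = cohort[outcome_col].to_numpy(float)
    Xc, names = build_design(cohort, covariates)
    indicators = np.column_stack([(bins == b).astype(float) for b in range(1, k)])
    ind_names = [f"{bin_col}_{b}" for b in range(1, k)]
    X = np.hstack([Xc[:, :1], indicators, Xc[:, 1:]])
    full_names = [names[0]] + ind_names + names[1:]
    w = None
    if weights is not None:
        w = weights.weights if isinstance(weights, IPWeights) else np.asarray(weights)
    full = fit_logistic(X, y, weights=w, feature_names=full_names)
    reduced = fit_logistic(Xc, y, weights=w, feature_names=names)
    lr = likelihood_ratio_test(full, reduced)
    rcov = sandwich_cov(full, X, y)
    estimates = []
    for i, b in enumerate(range(1, k)):
        beta = full.params[1 + i]
        se = float(np.sqrt(rcov[1 + i, 1 + i]))
        estimates.append(
            _wald_effect(
                beta,
                se,
                "doubly_robust" if weights is not None else "adjusted",
                int(counts[b]),
                int(counts[0]),
                label=f"bin {b} vs bin 0",
            )
        )
    return estimates, lr
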