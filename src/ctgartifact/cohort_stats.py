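"""Descriptive and elementary inferential statistics for the cohort.

Wilson score intervals for proportions, 2x2 odds ratios with Woolf
(log-scale) confidence intervals, the pooled two-proportion z test,
Pearson chi-square with Yates continuity correction, odds-ratio to
number-needed-to-treat conversion, and a normal-approximation sample
size for comparing two proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass
class ProportionCI:
    """A binomial proportion with a confidence interval."""

    k: int
    n: int
    point: float
    lo: float
    hi: float
    method: str = "wilson"


@dataclass
class TwoByTwo:
    """Cell counts: a = exposed event, b = exposed non-event,
    c = unexposed event, d = unexposed non-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")


@dataclass
class EffectEstimate:
    """An odds ratio with its 95% interval and Wald p-value."""

    or_value: float
    ci_lo: float
    ci_hi: float
    p: float
    method: str
    n_exposed: int = 0
    n_unexposed: int = 0
    label: str = ""


def wilson_ci(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    Unlike the Wald interval it is never empty at the boundaries and is
    symmetric in the complement: the interval for ``n - k`` successes is
    the reflection about 1/2 of the interval for ``k``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    return ProportionCI(k=k, n=n, point=k / n, lo=float(lo), hi=float(hi))


def odds_ratio_2x2(
    t: TwoByTwo, conf: float = 0.95, haldane: bool = False
) -> EffectEstimate:
    """Odds ratio (a·d)/(b·c) with Woolf log-scale CI and Wald p.

    A zero cell raises unless ``haldane`` adds the 0.5
    Haldane–Anscombe correction to every cell.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True for the 0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orv = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + conf / 2)
    log_or = np.log(orv)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return EffectEstimate(
        or_value=float(orv),
        ci_lo=float(np.exp(log_or - z * se)),
        ci_hi=float(np.exp(log_or + z * se)),
        p=float(p),
        method="unadjusted",
        n_exposed=t.a + t.b,
        n_unexposed=t.c + t.d,
    )


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test; returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1)")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def chi_square_2x2(t: TwoByTwo, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (df = 1); returns (statistic, p).

    Yates continuity correction is on by default, matching common
    practice for sparse outcome rows.
    """
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


def or_to_nnt(or_value: float, baseline_risk: float) -> int:
    """Number needed to treat implied by an odds ratio at a baseline risk.

    Converts the baseline risk to odds, scales by the OR, converts back,
    and returns round(1 / absolute risk difference).  The baseline
    convention is the overall cohort incidence.
    """
    if or_value <= 1:
        raise ValueError("NNT defined only for or_value > 1 (infinite at OR = 1)")
    if not 0 < baseline_risk < 1:
        raise ValueError("baseline_risk must be in (0, 1)")
    odds0 = baseline_risk / (1 - baseline_risk)
    odds1 = odds0 * or_value
    risk1 = odds1 / (1 + odds1)
    return int(round(1.0 / (risk1 - baseline_risk)))


def sample_size_two_proportions(
    p0: float,
    rel_increase: float,
    power: float = 0.80,
    alpha: float = 0.05,
    continuity: bool = False,
) -> int:
    """Per-group n to detect a relative increase in a proportion.

    Normal-approximation formula for two independent proportions with
    p1 = p0·(1 + rel_increase):

        n = [ z_{1-α/2}·sqrt(2·p̄·q̄) + z_{power}·sqrt(p0·q0 + p1·q1) ]²
            / (p1 − p0)²,   p̄ = (p0 + p1)/2

    With ``continuity`` the Fleiss correction
    n' = (n/4)·[1 + sqrt(1 + 4/(n·|p1−p0|))]² is applied.
    """
    p1 = p0 * (1 + rel_increase)
    if not 0 < p0 < p1 < 1:
        raise ValueError("need 0 < p0 < p0*(1+rel_increase) < 1")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    pbar = (p0 + p1) / 2
    delta = p1 - p0
    n = (za * np.sqrt(2 * pbar * (1 - pbar)) + zb * np.sqrt(p0 * (1 - p0) + p1 * (1 - p1))) ** 2 / delta**2
    if continuity:
        n = n / 4 * (1 + np.sqrt(1 + 4 / (n * delta))) ** 2
    return int(np.ceil(n))


def _is_binary(s: pd.Series) -> bool:
    vals = s.dropna().unique()
    return len(vals) <= 2 and set(pd.Series(vals).astype(float)) <= {0.0, 1.0}


def table_one(
    cohort: pd.DataFrame,
    strat_col: str = "exposure_high",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Baseline characteristics stratified by exposure.

    Continuous columns are summarised as median (IQR) and compared with
    the Mann-Whitney U test; binary columns as n (%, Wilson 95% CI)
    compared with the chi-square test.  One row per characteristic.
    """
    if strat_col not in cohort.columns:
        raise ValueError(f"stratification column {strat_col!r} not in cohort")
    g1 = cohort[cohort[strat_col].astype(bool)]
    g0 = cohort[~cohort[strat_col].astype(bool)]
    if columns is None:
        columns = [
            c
            for c in cohort.columns
            if c not in (strat_col, "episode_id")
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    rows = []
    for col in columns:
        s0, s1 = g0[col].dropna(), g1[col].dropna()
        if _is_binary(cohort[col]):
            k0, n0 = int(s0.sum()), len(s0)
            k1, n1 = int(s1.sum()), len(s1)
            ci0 = wilson_ci(k0, n0) if n0 else None
            ci1 = wilson_ci(k1, n1) if n1 else None
            try:
                _, p = chi_square_2x2(TwoByTwo(k1, n1 - k1, k0, n0 - k0))
            except ValueError:
                p = np.nan
            rows.append(
                dict(
                    characteristic=col,
                    kind="binary",
                    not_high=f"{k0} ({100 * k0 / n0:.2f}%, {100 * ci0.lo:.2f}-{100 * ci0.hi:.2f}%)",
                    high=f"{k1} ({100 * k1 / n1:.2f}%, {100 * ci1.lo:.2f}-{100 * ci1.hi:.2f}%)",
                    p_value=p,
                )
            )
        else:
            q0 = s0.quantile([0.5, 0.25, 0.75])
            q1 = s1.quantile([0.5, 0.25, 0.75])
            if len(s0) and len(s1):
                _, p = stats.mannwhitneyu(s0, s1, alternative="two-sided")
            else:
                p = np.nan
            rows.append(
                dict(
                    characteristic=col,
                    kind="continuous",
                    not_high=f"{q0[0.5]:.2f} ({q0[0.25]:.2f}-{q0[0.75]:.2f})",
                    high=f"{q1[0.5]:.2f} ({q1[0.25]:.2f}-{q1[0.75]:.2f})",
                    p_value=float(p),
                )
            )
    return pd.DataFrame(rows)
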