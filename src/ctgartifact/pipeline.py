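"""End-to-end study pipeline: quantify → classify → describe → estimate.

Orchestrates the full replication on a cohort table plus a directory of
raw trace files (or a precomputed per-episode metrics table): inclusion
and exclusion filters with a flow-diagram audit trail, composite outcome
classification, Table-1-style descriptives, unadjusted / adjusted /
doubly robust effects, the log-quantile dose–response analysis with its
likelihood-ratio test, stage-of-labor subgroup rows, and the
complete-case versus multiple-imputation sensitivity comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import signal_quality as sq
from .causal import (
    doubly_robust_effect,
    estimate_propensity,
    ipw_weights,
    balance_table,
    quantile_dose_response,
)
from .cohort_stats import EffectEstimate, TwoByTwo, odds_ratio_2x2, table_one
from .errors import ConfigurationError, EmptyCohortError
from .missing_data import impute_bmi, pool_rubin
from .outcome import classify_cohort
from .synthetic import (
    DEFAULT_OUTCOME_COVARIATES,
    DEFAULT_PROPENSITY_COVARIATES,
)

logger = logging.getLogger("ctgartifact")


@dataclass
class PipelineConfig:
    """Fixed analytic choices of the study plan."""

    dropout_thresh: float = sq.DROPOUT_THRESHOLD
    coincidence_thresh: float = sq.COINCIDENCE_THRESHOLD
    exclusion_dropout: float = sq.EXCLUSION_DROPOUT
    window_min: float = sq.WINDOW_MIN
    min_duration_min: float = sq.MIN_DURATION_MIN
    min_gestation_weeks: float = 36.0
    propensity_covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_PROPENSITY_COVARIATES)
    )
    outcome_covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_OUTCOME_COVARIATES)
    )
    quantile_k: int = 5
    mi_m: int = 20
    seed: int = 0
    stabilized_weights: bool = True
    truncate_pct: tuple[float, float] | None = (1.0, 99.0)
    exclusion_flags: list[str] = field(default_factory=list)
    run_imputation: bool = True
    run_dose_response: bool = True
    run_subgroups: bool = True

    def __post_init__(self) -> None:
        for name in ("dropout_thresh", "coincidence_thresh", "exclusion_dropout"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.window_min < self.min_duration_min:
            raise ConfigurationError("window_min must be >= min_duration_min")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "truncate_pct" in raw and raw["truncate_pct"] is not None:
            raw["truncate_pct"] = tuple(raw["truncate_pct"])
        return cls(**raw)


def _effect_row(label: str, est: EffectEstimate) -> dict:
    return dict(
        analysis=label,
        method=est.method,
        or_value=est.or_value,
        ci_lo=est.ci_lo,
        ci_hi=est.ci_hi,
        p=est.p,
        n_exposed=est.n_exposed,
        n_unexposed=est.n_unexposed,
    )


def _crude_2x2(df: pd.DataFrame) -> TwoByTwo:
    a = int((df.exposure_high & df.asphyxia).sum())
    b = int((df.exposure_high & ~df.asphyxia).sum())
    c = int((~df.exposure_high & df.asphyxia).sum())
    d = int((~df.exposure_high & ~df.asphyxia).sum())
    return TwoByTwo(a, b, c, d)


def _estimate_suite(
    df: pd.DataFrame, config: PipelineConfig, label_prefix: str = "primary"
) -> tuple[list[dict], pd.DataFrame | None]:
    """Unadjusted, adjusted, and doubly robust rows for one cohort."""
    rows = []
    rows.append(_effect_row(f"{label_prefix}_unadjusted", odds_ratio_2x2(_crude_2x2(df))))
    adj = doubly_robust_effect(df, config.outcome_covariates, weights=None)
    rows.append(_effect_row(f"{label_prefix}_adjusted", adj))
    ps = estimate_propensity(df, config.propensity_covariates)
    w = ipw_weights(
        ps.fitted,
        df["exposure_high"].to_numpy(bool),
        stabilized=config.stabilized_weights,
        truncate_pct=config.truncate_pct,
    )
    dr = doubly_robust_effect(df, config.outcome_covariates, w)
    rows.append(_effect_row(f"{label_prefix}_doubly_robust", dr))
    bal = balance_table(df, config.propensity_covariates, w)
    return rows, bal


def run_pipeline(
    config: PipelineConfig,
    cohort: pd.DataFrame | str | Path,
    traces: pd.DataFrame | str | Path | None = None,
) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    ``traces`` may be a directory of raw trace files, a precomputed
    per-episode metrics table (with ``dropout_fraction`` etc.), or
    ``None`` when the cohort table already carries ``exposure_high``
    and ``dropout_fraction`` columns.  Every filter logs counts in/out
    under ``audit``.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    cohort = cohort.copy()
    audit: list[dict] = []

    def step(name: str, before: int, df: pd.DataFrame) -> pd.DataFrame:
        audit.append(dict(filter=name, n_in=before, n_out=len(df), removed=before - len(df)))
        logger.info("%s: %d -> %d", name, before, len(df))
        if len(df) == 0:
            raise EmptyCohortError(f"no records remain after filter {name!r}")
        return df

    # signal metrics
    if traces is not None:
        if not isinstance(traces, pd.DataFrame):
            traces = sq.quantify_directory(
                traces,
                window_min=config.window_min,
                min_duration_min=config.min_duration_min,
                dropout_thresh=config.dropout_thresh,
                coincidence_thresh=config.coincidence_thresh,
                max_dropout=config.exclusion_dropout,
            )
        cohort = cohort.merge(
            traces[
                [
                    "episode_id",
                    "dropout_fraction",
                    "coincidence_fraction",
                    "window_minutes",
                    "excluded",
                    "exposure_high",
                    "rejected_short",
                ]
            ],
            on="episode_id",
            how="inner",
            suffixes=("_cohort", ""),
        )

    n0 = len(cohort)
    # inclusion: gestation
    if "gestation_weeks" in cohort.columns:
        cohort = step(
            f"gestation >= {config.min_gestation_weeks} weeks",
            n0,
            cohort[cohort.gestation_weeks >= config.min_gestation_weeks],
        )
    # configured clinical exclusions (multiple pregnancy, congenital anomaly...)
    for flag in config.exclusion_flags:
        if flag in cohort.columns:
            cohort = step(
                f"exclusion flag {flag}",
                len(cohort),
                cohort[~cohort[flag].astype(bool)],
            )
    # window rejection (too-short recordings)
    if "rejected_short" in cohort.columns:
        cohort = step(
            f"window >= {config.min_duration_min} min",
            len(cohort),
            cohort[~cohort.rejected_short.astype(bool)],
        )
    # >90% dropout exclusion
    if "excluded" in cohort.columns:
        cohort = step(
            f"dropout <= {config.exclusion_dropout:.0%}",
            len(cohort),
            cohort[~cohort.excluded.astype(bool)],
        )

    # composite outcome
    if "asphyxia" not in cohort.columns:
        cls = classify_cohort(cohort)
        cohort = pd.concat([cohort, cls], axis=1)
    if "exposure_high" not in cohort.columns:
        raise ConfigurationError(
            "cohort has no exposure_high column and no traces were supplied"
        )
    cohort["exposure_high"] = cohort["exposure_high"].astype(bool)
    cohort["asphyxia"] = cohort["asphyxia"].astype(bool)

    results: dict = {
        "config": asdict(config),
        "audit": audit,
        "n_analyzed": len(cohort),
        "n_exposed": int(cohort.exposure_high.sum()),
        "n_cases": int(cohort.asphyxia.sum()),
    }

    # descriptive table
    desc_cols = [
        c
        for c in (
            "age", "bmi", "gestation_weeks", "nulliparous", "spontaneous_onset",
            "labor_duration_h", "regional_anesthesia", "meconium",
            "birthweight_g", "infant_male", "asphyxia",
        )
        if c in cohort.columns
    ]
    results["table1"] = table_one(cohort, columns=desc_cols).to_dict("records")

    # complete-case analysis set
    cc = cohort.dropna(
        subset=[c for c in set(config.propensity_covariates + config.outcome_covariates)]
    ) if cohort[
        list(set(config.propensity_covariates + config.outcome_covariates))
    ].isna().any().any() else cohort
    if len(cc) < len(cohort):
        audit.append(
            dict(
                filter="complete-case covariates",
                n_in=len(cohort),
                n_out=len(cc),
                removed=len(cohort) - len(cc),
            )
        )

    effects, bal = _estimate_suite(cc, config)
    results["effects"] = effects
    results["balance"] = bal.to_dict("records")

    # quantile dose-response on dropout (needs per-episode dropout)
    if config.run_dose_response and "dropout_fraction" in cc.columns:
        labels, edges = sq.assign_log_quantile_bins(
            cc["dropout_fraction"].to_numpy(float), k=config.quantile_k
        )
        ccq = cc.copy()
        ccq["dropout_bin"] = labels
        ps = estimate_propensity(ccq, config.propensity_covariates)
        w = ipw_weights(
            ps.fitted,
            ccq["exposure_high"].to_numpy(bool),
            stabilized=config.stabilized_weights,
            truncate_pct=config.truncate_pct,
        )
        ests, lr = quantile_dose_response(
            ccq, "dropout_bin", config.outcome_covariates, w
        )
        results["dose_response"] = dict(
            bin_edges_pct=edges.tolist(),
            effects=[_effect_row(f"dropout_bin_{i + 1}", e) for i, e in enumerate(ests)],
            lr_statistic=lr.statistic,
            lr_df=lr.df,
            lr_p=lr.p,
        )

    # stage-of-labor subgroups
    if config.run_subgroups and {"stage1_present", "stage2_present"} <= set(
        cc.columns
    ):
        sub_rows = []
        stage1_only = cc[cc.stage1_present.astype(bool) & ~cc.stage2_present.astype(bool)]
        both = cc[cc.stage1_present.astype(bool) & cc.stage2_present.astype(bool)]
        for label, sub in (("stage1_only", stage1_only), ("both_stages", both)):
            if (
                sub.asphyxia.nunique() == 2
                and sub.exposure_high.nunique() == 2
                and len(sub) >= 200
            ):
                try:
                    rows, _ = _estimate_suite(sub, config, label)
                    sub_rows.extend(rows)
                except Exception as exc:  # noqa: BLE001 - degenerate subgroup
                    logger.warning("subgroup %s failed: %s", label, exc)
        results["subgroups"] = sub_rows

    # MI sensitivity (BMI is the only incomplete covariate)
    if (
        config.run_imputation
        and "bmi" in cohort.columns
        and cohort["bmi"].isna().any()
    ):
        preds = [
            c
            for c in set(config.propensity_covariates + config.outcome_covariates)
            if c != "bmi"
        ] + ["exposure_high", "asphyxia"]
        completed = impute_bmi(
            cohort, sorted(preds), m=config.mi_m, seed=config.seed
        )
        ests, vars_ = [], []
        for comp in completed:
            ps = estimate_propensity(comp, config.propensity_covariates)
            w = ipw_weights(
                ps.fitted,
                comp["exposure_high"].to_numpy(bool),
                stabilized=config.stabilized_weights,
                truncate_pct=config.truncate_pct,
            )
            e = doubly_robust_effect(comp, config.outcome_covariates, w)
            se = (np.log(e.ci_hi) - np.log(e.ci_lo)) / (2 * 1.959963984540054)
            ests.append(np.log(e.or_value))
            vars_.append(se**2)
        pooled = pool_rubin(np.array(ests), np.array(vars_))
        lo, hi = pooled.ci()
        results["imputation"] = dict(
            m=pooled.m,
            pooled_or=float(np.exp(pooled.pooled_estimate)),
            ci_lo=float(np.exp(lo)),
            ci_hi=float(np.exp(hi)),
            within_variance=pooled.within_variance,
            between_variance=pooled.between_variance,
            df=pooled.df,
        )

    return results


def format_forest(results: dict) -> str:
    """Plain-text forest table of every effect row in the report."""
    rows = list(results.get("effects", []))
    rows += results.get("subgroups", [])
    dr = results.get("dose_response")
    if dr:
        rows += dr["effects"]
    lines = [f"{'analysis':<28} {'OR':>6} {'95% CI':>16} {'p':>8}"]
    for r in rows:
        ci = f"{r['ci_lo']:.2f}-{r['ci_hi']:.2f}"
        lines.append(
            f"{r['analysis']:<28} {r['or_value']:>6.2f} {ci:>16} {r['p']:>8.3g}"
        )
    return "\n".join(lines)


def write_report(results: dict, out_dir) -> dict[str, Path]:
    """Write JSON + delimited-text + forest-table outputs; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    jpath = out_dir / "report.json"
    with open(jpath, "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    paths["json"] = jpath
    epath = out_dir / "effects.tsv"
    rows = list(results.get("effects", [])) + results.get("subgroups", [])
    if results.get("dose_response"):
        rows += results["dose_response"]["effects"]
    pd.DataFrame(rows).to_csv(epath, sep="\t", index=False)
    paths["effects"] = epath
    if "table1" in results:
        tpath = out_dir / "table1.tsv"
        pd.DataFrame(results["table1"]).to_csv(tpath, sep="\t", index=False)
        paths["table1"] = tpath
    fpath = out_dir / "forest.txt"
    fpath.write_text(format_forest(results) + "\n")
    paths["forest"] = fpath
    return paths
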