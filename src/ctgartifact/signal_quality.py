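"""Cumulative missing-valid-signal metrics for intrapartum CTG traces.

A cardiotocograph samples the fetal heart rate (FHR) at a nominal 4 Hz.
Two kinds of "missing valid signal" (artifact) are quantified here,
cumulatively over the analysis window:

* **dropout** — the monitor records FHR = 0 while signal acquisition is
  active in a live fetus;
* **maternal–fetal coincidence** ("confusion") — the recorded FHR lies
  within 5 bpm of the maternal heart rate (MHR), suggesting the transducer
  is tracking the mother.

Analysis is restricted to the final 60 minutes before delivery with a
minimum of 15 minutes of recording; records with more than 90% dropout are
excluded as uninterpretable.  An episode is classified as *high* missing
valid signal when dropout exceeds 30% or coincidence exceeds 1% (strict
inequalities).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TraceParseError, UndefinedMetricError

#: Default exposure / exclusion thresholds (proportions).
DROPOUT_THRESHOLD = 0.30
COINCIDENCE_THRESHOLD = 0.01
EXCLUSION_DROPOUT = 0.90
COINCIDENCE_BAND_BPM = 5.0
WINDOW_MIN = 60.0
MIN_DURATION_MIN = 15.0

#: Offset added inside the log before quantile binning, so zero-dropout
#: records land in the lowest bin (0.01% dropout on the percent scale).
LOG_EPS = 1e-4


@dataclass
class CTGRecord:
    """One labor episode's raw numeric trace.

    ``fhr`` holds heart-rate samples in bpm where 0 denotes dropout;
    ``mhr`` is the aligned maternal channel (0 = unavailable at that
    sample) or ``None`` when the monitor logged no maternal channel;
    ``acq_active`` marks samples during which the monitor was actively
    acquiring.  ``delivery_offset_s`` is the time of delivery measured
    from the first sample.
    """

    episode_id: str
    fhr: np.ndarray
    sampling_rate: float = 4.0
    mhr: np.ndarray | None = None
    acq_active: np.ndarray | None = None
    delivery_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        n = self.fhr.shape[0]
        if self.sampling_rate <= 0:
            raise TraceParseError(
                f"{self.episode_id}: sampling_rate must be positive, "
                f"got {self.sampling_rate}"
            )
        if self.mhr is not None:
            self.mhr = np.asarray(self.mhr, dtype=float)
            if self.mhr.shape[0] != n:
                raise TraceParseError(
                    f"{self.episode_id}: mhr length {self.mhr.shape[0]} "
                    f"!= fhr length {n}"
                )
        if self.acq_active is not None:
            self.acq_active = np.asarray(self.acq_active, dtype=bool)
            if self.acq_active.shape[0] != n:
                raise TraceParseError(
                    f"{self.episode_id}: acq_active length "
                    f"{self.acq_active.shape[0]} != fhr length {n}"
                )
        bad = np.flatnonzero((self.fhr < 0) | (self.fhr >= 300))
        if bad.size:
            raise TraceParseError(
                f"{self.episode_id}: fhr value {self.fhr[bad[0]]} out of "
                f"range [0, 300) at row {int(bad[0])}"
            )
        if self.mhr is not None:
            bad = np.flatnonzero((self.mhr < 0) | (self.mhr >= 300))
            if bad.size:
                raise TraceParseError(
                    f"{self.episode_id}: mhr value {self.mhr[bad[0]]} out of "
                    f"range [0, 300) at row {int(bad[0])}"
                )
        dur = n / self.sampling_rate
        if self.delivery_offset_s < 0 or self.delivery_offset_s > dur + 1e-9:
            raise TraceParseError(
                f"{self.episode_id}: delivery_offset_s "
                f"{self.delivery_offset_s} outside trace duration [0, {dur:.1f}]"
            )

    @property
    def duration_s(self) -> float:
        return self.fhr.shape[0] / self.sampling_rate


@dataclass
class AnalysisWindow:
    """The sub-trace covering up to the final 60 minutes before delivery."""

    episode_id: str
    fhr: np.ndarray
    sampling_rate: float
    mhr: np.ndarray | None = None
    acq_active: np.ndarray | None = None

    @property
    def active_mask(self) -> np.ndarray:
        if self.acq_active is None:
            return np.ones(self.fhr.shape[0], dtype=bool)
        return self.acq_active

    @property
    def active_sample_count(self) -> int:
        return int(self.active_mask.sum())

    @property
    def duration_min(self) -> float:
        return self.fhr.shape[0] / self.sampling_rate / 60.0


@dataclass
class SignalQualityMetrics:
    """Cumulative artifact fractions and classification for one episode.

    ``coincidence_fraction`` is ``None`` when no maternal channel exists
    (e.g. externally validated datasets without MHR).  ``exposure_high``
    is meaningful only when ``excluded`` is False.
    """

    episode_id: str
    dropout_fraction: float
    coincidence_fraction: float | None
    exposure_high: bool
    excluded: bool
    window_minutes: float


def load_ctg_file(path: str | Path) -> CTGRecord:
    """Read one delimited trace file into a validated :class:`CTGRecord`.

    The format is plain CSV with a mandatory header row holding columns
    ``t_s``, ``fhr_bpm`` and optionally ``mhr_bpm`` and ``acq_active``,
    preceded by ``# key=value`` comment lines carrying at least
    ``delivery_offset_s`` and optionally ``sampling_rate``.
    """
    path = Path(path)
    if not path.exists():
        raise TraceParseError(f"trace file not found: {path}")
    header: dict[str, float] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    try:
                        header[key.strip()] = float(val)
                    except ValueError as exc:
                        raise TraceParseError(
                            f"{path.name}: malformed header field {stripped!r}"
                        ) from exc
            else:
                body.write(line)
    body.seek(0)
    try:
        df = pd.read_csv(body)
    except Exception as exc:  # noqa: BLE001 - any csv failure is a parse error
        raise TraceParseError(f"{path.name}: unreadable CSV body: {exc}") from exc
    for col in ("t_s", "fhr_bpm"):
        if col not in df.columns:
            raise TraceParseError(f"{path.name}: missing required column {col!r}")
    if "delivery_offset_s" not in header:
        raise TraceParseError(
            f"{path.name}: missing 'delivery_offset_s' header field"
        )
    t = df["t_s"].to_numpy(float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise TraceParseError(f"{path.name}: t_s not strictly increasing at row {row}")
    if df["fhr_bpm"].isna().any():
        row = int(df["fhr_bpm"].isna().idxmax())
        raise TraceParseError(f"{path.name}: missing fhr_bpm at row {row}")
    neg = df.index[df["fhr_bpm"] < 0]
    if len(neg):
        raise TraceParseError(
            f"{path.name}: negative fhr_bpm at row {int(neg[0])}"
        )
    sampling_rate = header.get("sampling_rate", 4.0)
    mhr = df["mhr_bpm"].to_numpy(float) if "mhr_bpm" in df.columns else None
    acq = (
        df["acq_active"].to_numpy(float).astype(bool)
        if "acq_active" in df.columns
        else None
    )
    return CTGRecord(
        episode_id=path.stem,
        fhr=df["fhr_bpm"].to_numpy(float),
        sampling_rate=sampling_rate,
        mhr=mhr,
        acq_active=acq,
        delivery_offset_s=header["delivery_offset_s"],
    )


def extract_analysis_window(
    record: CTGRecord,
    window_min: float = WINDOW_MIN,
    min_duration_min: float = MIN_DURATION_MIN,
) -> AnalysisWindow | None:
    """Slice the final ``window_min`` minutes before delivery.

    Returns ``None`` (a rejection, not an error) when less than
    ``min_duration_min`` minutes of recording fall inside the window.
    The window is anchored to the delivery time, not the end of trace.
    The 15-minute minimum is inclusive: exactly 15 min is accepted.
    """
    fs = record.sampling_rate
    end = int(round(record.delivery_offset_s * fs))
    end = min(end, record.fhr.shape[0])
    start = max(0, end - int(round(window_min * 60 * fs)))
    n = end - start
    if n / fs / 60.0 < min_duration_min:
        return None
    return AnalysisWindow(
        episode_id=record.episode_id,
        fhr=record.fhr[start:end],
        sampling_rate=fs,
        mhr=None if record.mhr is None else record.mhr[start:end],
        acq_active=None if record.acq_active is None else record.acq_active[start:end],
    )


def compute_dropout_fraction(window: AnalysisWindow) -> float:
    """Fraction of acquisition-active samples recorded as FHR = 0."""
    active = window.active_mask
    n_active = int(active.sum())
    if n_active == 0:
        raise UndefinedMetricError(
            f"{window.episode_id}: no acquisition-active samples in window"
        )
    return float(np.count_nonzero(window.fhr[active] == 0) / n_active)


def compute_coincidence_fraction(
    window: AnalysisWindow, band_bpm: float = COINCIDENCE_BAND_BPM
) -> float | None:
    """Fraction of active samples with |FHR − MHR| < ``band_bpm``.

    Only samples where both channels carry signal (FHR > 0 and MHR > 0)
    can coincide; a dropout sample is never also a coincidence sample.
    The denominator is the same active-sample count used for dropout, so
    the two fractions are directly comparable.  Returns ``None`` when
    the record has no maternal channel.
    """
    if window.mhr is None:
        return None
    active = window.active_mask
    n_active = int(active.sum())
    if n_active == 0:
        raise UndefinedMetricError(
            f"{window.episode_id}: no acquisition-active samples in window"
        )
    fhr = window.fhr[active]
    mhr = window.mhr[active]
    hit = (fhr > 0) & (mhr > 0) & (np.abs(fhr - mhr) < band_bpm)
    return float(np.count_nonzero(hit) / n_active)


def classify_exposure(
    dropout_fraction: float,
    coincidence_fraction: float | None,
    dropout_thresh: float = DROPOUT_THRESHOLD,
    coincidence_thresh: float = COINCIDENCE_THRESHOLD,
) -> bool:
    """High missing valid signal: dropout > 30% OR coincidence > 1%.

    Thresholds are strict inequalities; a record at exactly the
    threshold is not exposed.  An absent coincidence channel can only
    leave the dropout rule in force.
    """
    if dropout_fraction > dropout_thresh:
        return True
    return coincidence_fraction is not None and coincidence_fraction > coincidence_thresh


def passes_quality_filter(
    dropout_fraction: float, max_dropout: float = EXCLUSION_DROPOUT
) -> bool:
    """False iff dropout exceeds 90% (strict), the predefined exclusion."""
    return not dropout_fraction > max_dropout


def compute_metrics(
    record: CTGRecord,
    window_min: float = WINDOW_MIN,
    min_duration_min: float = MIN_DURATION_MIN,
    band_bpm: float = COINCIDENCE_BAND_BPM,
    dropout_thresh: float = DROPOUT_THRESHOLD,
    coincidence_thresh: float = COINCIDENCE_THRESHOLD,
    max_dropout: float = EXCLUSION_DROPOUT,
    precomputed_coincidence: float | None = None,
) -> SignalQualityMetrics | None:
    """Window → fractions → classification for one episode.

    Returns ``None`` when the analysis window is rejected (shorter than
    the minimum duration).  ``precomputed_coincidence`` accepts a
    monitor-logged coincidence fraction for records whose maternal
    channel is not re-supplied.
    """
    window = extract_analysis_window(record, window_min, min_duration_min)
    if window is None:
        return None
    dropout = compute_dropout_fraction(window)
    if precomputed_coincidence is not None:
        coincidence: float | None = precomputed_coincidence
    else:
        coincidence = compute_coincidence_fraction(window, band_bpm)
    excluded = not passes_quality_filter(dropout, max_dropout)
    exposure = False if excluded else classify_exposure(
        dropout, coincidence, dropout_thresh, coincidence_thresh
    )
    return SignalQualityMetrics(
        episode_id=record.episode_id,
        dropout_fraction=dropout,
        coincidence_fraction=coincidence,
        exposure_high=exposure,
        excluded=excluded,
        window_minutes=window.duration_min,
    )


def quantify_directory(
    trace_dir: str | Path,
    **metric_kwargs,
) -> pd.DataFrame:
    """Per-episode metrics table for every ``*.csv`` trace in a directory.

    Rejected (too-short) records appear with NaN fractions and
    ``window_minutes`` = NaN so the caller retains the audit trail.
    """
    rows = []
    for path in sorted(Path(trace_dir).glob("*.csv")):
        record = load_ctg_file(path)
        m = compute_metrics(record, **metric_kwargs)
        if m is None:
            rows.append(
                dict(
                    episode_id=record.episode_id,
                    dropout_fraction=np.nan,
                    coincidence_fraction=np.nan,
                    window_minutes=np.nan,
                    excluded=True,
                    exposure_high=False,
                    rejected_short=True,
                )
            )
        else:
            rows.append(
                dict(
                    episode_id=m.episode_id,
                    dropout_fraction=m.dropout_fraction,
                    coincidence_fraction=(
                        np.nan
                        if m.coincidence_fraction is None
                        else m.coincidence_fraction
                    ),
                    window_minutes=m.window_minutes,
                    excluded=m.excluded,
                    exposure_high=m.exposure_high,
                    rejected_short=False,
                )
            )
    return pd.DataFrame(rows)


def assign_log_quantile_bins(
    dropouts: Sequence[float] | np.ndarray,
    k: int = 5,
    eps: float = LOG_EPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count quantile bins of log-transformed dropout ("log-Q").

    Returns ``(labels, edges_pct)``: integer bin labels 0..k-1 (0 = lowest
    dropout, the reference category for dose–response models) and the
    k+1 bin edges mapped back to the percent scale.  Because the log is
    strictly monotone, membership is identical to quantile bins on the
    raw fractions; the transform matters for how edges are reported and
    for any downstream treatment of the binned variable as continuous.
    """
    x = np.asarray(dropouts, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ConfigurationError("dropout fractions must lie in [0, 1]")
    if k < 2:
        raise ConfigurationError(f"bin count k must be >= 2, got {k}")
    if np.unique(x).size < k:
        raise ConfigurationError(
            f"need at least k={k} distinct dropout values, got {np.unique(x).size}"
        )
    logx = np.log(x + eps)
    try:
        labels, edges = pd.qcut(logx, k, labels=False, retbins=True, duplicates="raise")
    except ValueError as exc:
        raise ConfigurationError(f"quantile bin edges not unique: {exc}") from exc
    edges_pct = (np.exp(edges) - eps) * 100.0
    edges_pct[0] = max(edges_pct[0], 0.0)
    return labels.astype(int), edges_pct
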