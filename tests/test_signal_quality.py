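"""Signal-quality metrics: windowing, dropout, coincidence, binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctgartifact import signal_quality as sq
from ctgartifact.errors import (
    ConfigurationError,
    TraceParseError,
    UndefinedMetricError,
)

from conftest import make_record, make_window


class TestLoadCtgFile:
    def test_round_trips_a_full_hour_trace(self, trace_file_factory):
        path = trace_file_factory(n=14400, mhr=np.full(14400, 80.0))
        rec = sq.load_ctg_file(path)
        assert rec.fhr.shape[0] == 14400
        assert rec.mhr is not None and rec.mhr[0] == 80.0
        assert rec.delivery_offset_s == pytest.approx(3600.0)

    def test_absent_mhr_column_marks_channel_unavailable(self, trace_file_factory):
        rec = sq.load_ctg_file(trace_file_factory(n=100))
        assert rec.mhr is None

    def test_negative_fhr_names_the_row(self, trace_file_factory):
        fhr = np.full(50, 140.0)
        fhr[17] = -5.0
        with pytest.raises(TraceParseError, match="row 17"):
            sq.load_ctg_file(trace_file_factory(fhr=fhr, n=50))

    def test_missing_delivery_offset_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t_s,fhr_bpm\n0.0,140\n0.25,141\n")
        with pytest.raises(TraceParseError, match="delivery_offset_s"):
            sq.load_ctg_file(p)

    def test_misaligned_channels_rejected_at_construction(self):
        with pytest.raises(TraceParseError, match="mhr length"):
            sq.CTGRecord(
                episode_id="x",
                fhr=np.full(10, 140.0),
                mhr=np.full(9, 80.0),
                delivery_offset_s=2.0,
            )


class TestExtractAnalysisWindow:
    def test_ninety_minute_trace_yields_final_hour(self):
        rec = make_record(n=90 * 60 * 4)
        win = sq.extract_analysis_window(rec)
        assert win is not None
        assert win.duration_min == pytest.approx(60.0)

    def test_ten_minute_trace_rejected(self):
        assert sq.extract_analysis_window(make_record(n=10 * 60 * 4)) is None

    def test_exactly_fifteen_minutes_accepted(self):
        win = sq.extract_analysis_window(make_record(n=15 * 60 * 4))
        assert win is not None
        assert win.duration_min == pytest.approx(15.0)

    def test_window_anchored_to_delivery_not_end_of_trace(self):
        # delivery 30 min before end of a 2 h trace: window is minutes 30-90
        n = 120 * 60 * 4
        fhr = np.full(n, 140.0)
        fhr[: 90 * 60 * 4] = 120.0  # value switch exactly at delivery-60min
        rec = sq.CTGRecord(
            episode_id="x", fhr=fhr, delivery_offset_s=90 * 60.0
        )
        win = sq.extract_analysis_window(rec)
        assert win.duration_min == pytest.approx(60.0)
        assert win.fhr[-1] == 120.0  # ends at delivery, not trace end

    def test_never_longer_than_window(self):
        rec = make_record(n=200 * 60 * 4)
        win = sq.extract_analysis_window(rec)
        assert win.duration_min <= 60.0 + 1e-9


class TestDropoutFraction:
    def test_quarter_of_active_samples_zero(self):
        fhr = np.full(240, 140.0)
        fhr[:60] = 0.0
        assert sq.compute_dropout_fraction(make_window(fhr)) == pytest.approx(0.25)

    def test_no_zeros_gives_zero(self):
        assert sq.compute_dropout_fraction(make_window(np.full(100, 150.0))) == 0.0

    def test_inactive_samples_leave_denominator(self):
        # 40 zeros among 400 active samples; 100 trailing inactive
        fhr = np.full(500, 140.0)
        fhr[:40] = 0.0
        acq = np.ones(500, bool)
        acq[400:] = False
        win = make_window(fhr, acq=acq)
        # independent per-sample counting oracle
        zeros = sum(1 for v, a in zip(fhr, acq) if a and v == 0)
        active = sum(1 for a in acq if a)
        assert sq.compute_dropout_fraction(win) == pytest.approx(zeros / active)
        assert sq.compute_dropout_fraction(win) == pytest.approx(0.10)

    def test_zero_active_samples_is_undefined(self):
        win = make_window(np.full(10, 140.0), acq=np.zeros(10, bool))
        with pytest.raises(UndefinedMetricError):
            sq.compute_dropout_fraction(win)


class TestCoincidenceFraction:
    def test_identical_channels_give_one(self):
        fhr = np.full(100, 90.0)
        assert sq.compute_coincidence_fraction(make_window(fhr, mhr=fhr)) == 1.0

    def test_absent_mhr_returns_none(self):
        assert sq.compute_coincidence_fraction(make_window(np.full(10, 140.0))) is None

    def test_constructed_counts_match_per_sample_oracle(self, rng):
        n = 240
        fhr = np.full(n, 140.0)
        mhr = np.full(n, 80.0)
        close = rng.choice(n, 12, replace=False)
        mhr[close] = fhr[close] - rng.uniform(0, 4.9, 12)
        win = make_window(fhr, mhr=mhr)
        oracle = sum(
            1 for f, m in zip(fhr, mhr) if f > 0 and m > 0 and abs(f - m) < 5
        ) / n
        assert sq.compute_coincidence_fraction(win) == pytest.approx(oracle)
        assert sq.compute_coincidence_fraction(win) == pytest.approx(0.05)

    def test_dropout_sample_never_counts_as_coincidence(self):
        fhr = np.zeros(100)
        mhr = np.full(100, 3.0)  # |0-3| < 5 but FHR is dropout
        assert sq.compute_coincidence_fraction(make_window(fhr, mhr=mhr)) == 0.0

    @given(
        st.integers(20, 200),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fractions_match_brute_force_on_random_traces(self, n, seed):
        r = np.random.default_rng(seed)
        fhr = r.choice([0.0, 80.0, 140.0], n, p=[0.2, 0.2, 0.6])
        mhr = r.uniform(70, 150, n)
        acq = r.random(n) < 0.9
        if not acq.any():
            acq[0] = True
        win = make_window(fhr, mhr=mhr, acq=acq)
        active = [i for i in range(n) if acq[i]]
        drop = sum(1 for i in active if fhr[i] == 0) / len(active)
        coinc = sum(
            1 for i in active if fhr[i] > 0 and mhr[i] > 0 and abs(fhr[i] - mhr[i]) < 5
        ) / len(active)
        assert sq.compute_dropout_fraction(win) == pytest.approx(drop)
        assert sq.compute_coincidence_fraction(win) == pytest.approx(coinc)
        assert 0.0 <= drop <= 1.0 and 0.0 <= coinc <= 1.0


class TestClassification:
    @pytest.mark.parametrize(
        "dropout,coincidence,expected",
        [
            (0.35, 0.0, True),   # >30% dropout
            (0.10, 0.02, True),  # >1% coincidence
            (0.30, 0.01, False), # boundaries are strict
            (0.10, None, False), # no maternal channel, low dropout
            (0.31, None, True),
        ],
    )
    def test_exposure_rule(self, dropout, coincidence, expected):
        assert sq.classify_exposure(dropout, coincidence) is expected

    def test_exposure_monotone_in_both_fractions(self):
        grid = np.linspace(0, 1, 21)
        for lo, hi in zip(grid[:-1], grid[1:]):
            assert sq.classify_exposure(lo, 0.0) <= sq.classify_exposure(hi, 0.0)
            assert sq.classify_exposure(0.0, lo) <= sq.classify_exposure(0.0, hi)

    @pytest.mark.parametrize(
        "dropout,retained", [(0.95, False), (0.90, True), (0.0, True)]
    )
    def test_quality_filter_strict_at_ninety_percent(self, dropout, retained):
        assert sq.passes_quality_filter(dropout) is retained


class TestLogQuantileBins:
    def test_equal_count_bins(self):
        vals = np.arange(0.01, 1.001, 0.01)
        labels, edges = sq.assign_log_quantile_bins(vals, k=5)
        assert np.bincount(labels).tolist() == [20, 20, 20, 20, 20]
        assert edges.shape == (6,)

    def test_membership_invariant_under_log_transform(self, rng):
        vals = rng.beta(1.5, 6, 500)
        labels, _ = sq.assign_log_quantile_bins(vals, k=5)
        # quantile bins on the raw values (strictly monotone transform of log)
        import pandas as pd

        raw_labels = pd.qcut(vals, 5, labels=False)
        assert np.array_equal(labels, raw_labels)

    def test_top_edge_matches_sort_based_percentile_oracle(self, rng):
        vals = rng.uniform(0.001, 0.9, 1000)
        _, edges = sq.assign_log_quantile_bins(vals, k=5)
        srt = np.sort(vals)
        # pandas qcut uses linear-interpolation percentiles; compare on percent scale
        oracle = np.percentile(vals, 80) * 100
        assert edges[4] == pytest.approx(oracle, rel=1e-6)
        assert edges[5] == pytest.approx(srt[-1] * 100, rel=1e-6)

    def test_bin_counts_never_differ_by_more_than_one(self, rng):
        vals = rng.beta(2, 5, 503)
        labels, _ = sq.assign_log_quantile_bins(vals, k=5)
        counts = np.bincount(labels)
        assert counts.max() - counts.min() <= 1

    def test_too_few_distinct_values_is_config_error(self):
        with pytest.raises(ConfigurationError):
            sq.assign_log_quantile_bins([0.1, 0.1, 0.1, 0.2], k=5)
        with pytest.raises(ConfigurationError):
            sq.assign_log_quantile_bins(np.linspace(0, 1, 50), k=1)


class TestComputeMetrics:
    def test_high_dropout_record_excluded_not_exposed(self):
        fhr = np.full(15 * 60 * 4, 0.0)
        fhr[: 60] = 140.0  # 98% dropout
        rec = sq.CTGRecord(episode_id="x", fhr=fhr, delivery_offset_s=900.0)
        m = sq.compute_metrics(rec)
        assert m.excluded and not m.exposure_high

    def test_short_record_rejected_returns_none(self):
        assert sq.compute_metrics(make_record(n=10 * 60 * 4)) is None

    def test_precomputed_coincidence_path(self):
        rec = make_record(n=15 * 60 * 4)
        m = sq.compute_metrics(rec, precomputed_coincidence=0.02)
        assert m.coincidence_fraction == 0.02
        assert m.exposure_high  # >1% coincidence from the monitor log
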