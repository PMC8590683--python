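"""Standardization, cumulative-time segmentation, and segment labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apneascreen import io, preprocessing
from apneascreen.io import EventAnnotation, RRISeries


def naive_segment_bounds(intervals, w):
    """Independent O(N*M) cumulative-sum scan for (k_n, j_n), 1-based."""
    c = np.cumsum(intervals)
    n_windows = int(c[-1] // w)
    bounds = []
    for n in range(1, n_windows + 1):
        k = next(i + 1 for i in range(len(intervals)) if c[i] > w * (n - 1))
        j = max(i + 1 for i in range(len(intervals)) if c[i] <= w * n)
        bounds.append((k, j))
    return bounds


class TestStandardize:
    def test_symmetric_three_point_case(self):
        out = preprocessing.standardize_rri(RRISeries("s", [0.8, 1.0, 1.2]))
        # sample sd of [0.8, 1.0, 1.2] is 0.2, so the outputs are -1, 0, 1
        assert np.allclose(out, [-1.0, 0.0, 1.0])

    def test_constant_series_raises(self):
        with pytest.raises(io.ValidationError, match="zero variance"):
            preprocessing.standardize_rri(RRISeries("s", [1.0, 1.0, 1.0]))

    def test_too_short_raises(self):
        with pytest.raises(io.ValidationError):
            preprocessing.standardize_rri(RRISeries("s", [1.0]))

    def test_moment_oracle(self, rng):
        series = RRISeries("s", rng.uniform(0.5, 1.2, size=1000))
        out = preprocessing.standardize_rri(series)
        assert abs(out.mean()) < 1e-9
        assert abs(np.var(out, ddof=1) - 1.0) < 1e-9


class TestSegmentation:
    def _segment(self, intervals, w=60.0, sid="s"):
        # bounds depend on raw cumulative time only, so feeding the raw
        # values as the "standardized" vector keeps these tests focused
        series = RRISeries(sid, intervals)
        return preprocessing.segment_rri(series, series.intervals, w)

    def test_uniform_record_splits_at_boundaries(self):
        # boundary cumsum ties close the earlier window
        segset = self._segment(np.ones(120))
        assert len(segset) == 2
        assert [s.n_beats for s in segset.segments] == [60, 60]
        assert (segset.segments[0].first_beat, segset.segments[0].last_beat) == (1, 60)
        assert (segset.segments[1].first_beat, segset.segments[1].last_beat) == (61, 120)

    def test_trailing_partial_window_discarded(self):
        segset = self._segment(np.ones(150))
        assert len(segset) == 2

    def test_window_bounds_are_nominal(self):
        segset = self._segment(np.random.default_rng(0).uniform(0.5, 1.2, 500), w=60.0)
        for seg in segset.segments:
            assert seg.end_s - seg.start_s == pytest.approx(60.0)

    def test_record_shorter_than_window_raises(self):
        with pytest.raises(io.ValidationError, match="shorter"):
            self._segment([1.0, 1.1, 0.9], w=60.0)

    def test_bounds_match_naive_scan_large_random(self, rng):
        intervals = rng.uniform(0.5, 1.2, size=10_000)
        segset = self._segment(intervals)
        expected = naive_segment_bounds(intervals, 60.0)
        got = [(s.first_beat, s.last_beat) for s in segset.segments]
        assert got == expected
        # each window's beats cover nearly the whole wall-clock window
        c = np.concatenate(([0.0], np.cumsum(intervals)))
        for seg in segset.segments:
            covered = c[seg.last_beat] - c[seg.first_beat - 1]
            assert covered >= 58.8

    def test_standardized_values_and_raw_values_align(self, rng):
        intervals = rng.uniform(0.5, 1.2, size=800)
        series = RRISeries("s", intervals)
        std = preprocessing.standardize_rri(series)
        segset = preprocessing.segment_rri(series, std, 60.0)
        for seg in segset.segments:
            assert np.array_equal(seg.values, std[seg.first_beat - 1 : seg.last_beat])
            assert np.array_equal(
                seg.raw_values, intervals[seg.first_beat - 1 : seg.last_beat]
            )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_property_appending_beats_never_changes_earlier_segments(self, seed):
        rng = np.random.default_rng(seed)
        intervals = rng.uniform(0.5, 1.2, size=300)
        base = self._segment(intervals, w=60.0)
        extended = self._segment(np.concatenate([intervals, [0.9, 0.8]]), w=60.0)
        # standardization changes values, but the beat-index bounds are a
        # function of cumulative time only
        for a, b in zip(base.segments, extended.segments):
            assert (a.first_beat, a.last_beat) == (b.first_beat, b.last_beat)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_property_bounds_match_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        intervals = rng.uniform(0.3, 1.9, size=int(rng.integers(80, 400)))
        if intervals.sum() < 60:
            intervals = np.concatenate([intervals, np.full(100, 0.9)])
        segset = self._segment(intervals)
        assert [(s.first_beat, s.last_beat) for s in segset.segments] == \
            naive_segment_bounds(intervals, 60.0)


class TestLabels:
    def _segset(self, n_windows=2, w=60.0):
        intervals = np.random.default_rng(1).uniform(0.8, 1.0, size=int(n_windows * w + 20))
        series = RRISeries("s", intervals)
        return preprocessing.segment_rri(
            series, preprocessing.standardize_rri(series), w
        )

    def test_no_events_all_normal(self):
        segset = preprocessing.label_segments(self._segset(), [])
        assert set(segset.labels) == {"N"}

    def test_full_coverage_is_apnea(self):
        segset = preprocessing.label_segments(
            self._segset(), [EventAnnotation(0.0, 60.0, "apnea")]
        )
        assert segset.labels[0] == "A"

    @pytest.mark.parametrize(
        "onset,duration,expected",
        [
            (55.0, 12.0, ("N", "N")),  # overlaps 5 s and 7 s
            (50.0, 25.0, ("A", "A")),  # overlaps 10 s and 15 s
        ],
    )
    def test_overlap_arithmetic_at_the_10s_rule(self, onset, duration, expected):
        segset = preprocessing.label_segments(
            self._segset(), [EventAnnotation(onset, duration, "apnea")]
        )
        assert tuple(segset.labels[:2]) == expected

    def test_hypopnea_counts_arrhythmia_does_not(self):
        events = [
            EventAnnotation(0.0, 30.0, "hypopnea"),
            EventAnnotation(60.0, 60.0, "arrhythmia"),
        ]
        segset = preprocessing.label_segments(self._segset(), events)
        assert segset.labels[0] == "A"
        assert segset.labels[1] == "N"

    def test_overlapping_apnea_and_hypopnea_not_double_counted(self):
        # two 6-s events covering the same 6 s: union coverage is 6 s < 10 s
        events = [
            EventAnnotation(10.0, 6.0, "apnea"),
            EventAnnotation(10.0, 6.0, "hypopnea"),
        ]
        segset = preprocessing.label_segments(self._segset(), events)
        assert segset.labels[0] == "N"

    def test_label_overlap_threshold_is_configurable(self):
        events = [EventAnnotation(0.0, 6.0, "apnea")]
        strict = preprocessing.label_segments(self._segset(), events, label_overlap_s=5.0)
        assert strict.labels[0] == "A"
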