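"""Confusion metrics, frame truth, and event-level capture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from eeganomaly import (
    ConfusionCounts,
    FrameConfig,
    frame_truth,
    confusion,
    compute_metrics,
    event_capture,
    combine_channel_flags,
)
from eeganomaly.evaluation import micro_average

counts_st = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 500),
    fp=st.integers(0, 500),
    tn=st.integers(0, 500),
    fn=st.integers(0, 500),
)


class TestComputeMetrics:
    def test_hand_computed_case(self):
        r = compute_metrics(ConfusionCounts(tp=40, fn=10, tn=80, fp=20))
        assert r.sensitivity == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.8)
        assert r.ppv == pytest.approx(2 / 3)
        assert r.accuracy == pytest.approx(0.8)

    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=30, tn=70))
        assert (
            r.sensitivity == r.specificity == r.accuracy == r.f1 == r.mcc == 1.0
        )
        assert r.fpr == r.fnr == r.fdr == r.fomr == 0.0

    def test_zero_denominator_reported_as_undefined(self):
        r = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=10, fp=5))
        assert r.sensitivity is None
        assert r.fnr is None
        assert r.specificity is not None

    def test_inverted_classifier_mcc(self):
        r = compute_metrics(ConfusionCounts(tp=0, fn=30, tn=0, fp=70))
        assert r.mcc == pytest.approx(-1.0)

    @given(counts_st)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_complementarity_identities(self, c):
        r = compute_metrics(c)
        if r.specificity is not None:
            assert r.fpr + r.specificity == pytest.approx(1.0)
        if r.sensitivity is not None:
            assert r.fnr + r.sensitivity == pytest.approx(1.0)
        if r.ppv is not None:
            assert r.fdr + r.ppv == pytest.approx(1.0)
        if r.npv is not None:
            assert r.fomr + r.npv == pytest.approx(1.0)
        if r.mcc is not None:
            assert -1.0 - 1e-12 <= r.mcc <= 1.0 + 1e-12

    def test_mcc_equals_pearson_correlation_of_labels(self, rng):
        for _ in range(20):
            flags = rng.random(300) < 0.3
            truth = rng.random(300) < 0.2
            r = compute_metrics(confusion(flags, truth))
            if r.mcc is None:
                continue
            assert r.mcc == pytest.approx(
                np.corrcoef(flags, truth)[0, 1], abs=1e-12
            )
            assert r.mcc == pytest.approx(
                matthews_corrcoef(truth, flags), abs=1e-9
            )


class TestConfusion:
    def test_perfect_and_inverted_agreement(self, rng):
        truth = rng.random(100) < 0.4
        c = confusion(truth, truth)
        assert c.fp == c.fn == 0
        c = confusion(~truth, truth)
        assert c.tp == c.tn == 0

    def test_counts_match_elementwise_tally(self, rng):
        flags = rng.random(1000) < 0.5
        truth = rng.random(1000) < 0.5
        c = confusion(flags, truth)
        assert c.tp == sum(f and t for f, t in zip(flags, truth))
        assert c.fp == sum(f and not t for f, t in zip(flags, truth))
        assert c.tn == sum(not f and not t for f, t in zip(flags, truth))
        assert c.fn == sum(not f and t for f, t in zip(flags, truth))
        assert c.total == 1000

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion(np.zeros(5, bool), np.zeros(6, bool))

    def test_micro_average_sums_counts(self):
        a = ConfusionCounts(1, 2, 3, 4)
        b = ConfusionCounts(10, 20, 30, 40)
        r = micro_average([a, b])
        assert r.counts == ConfusionCounts(11, 22, 33, 44)


class TestFrameTruth:
    CFG = FrameConfig()  # window 256, hop 192

    def _times(self, n):
        return np.arange(n) * self.CFG.hop

    def test_event_covering_exact_frames(self):
        # event spans samples [1984, 2496): inside frames 10-12 but clear
        # of the overlap zones shared with frames 9 and 13
        times = self._times(20)
        truth = frame_truth([(1984 / 256, 2496 / 256)], times, self.CFG)
        assert truth[10] and truth[11] and truth[12]
        assert truth.sum() == 3

    def test_single_sample_event_hits_one_frame(self):
        times = self._times(20)
        # sample 5*192+300 = 1260 lies only in frame 5 ([960,1216)? no)
        # choose sample inside exactly one frame: frame k covers
        # [192k, 192k+256); overlap zones are [192(k+1), 192k+256).
        sample = 5 * 192 + 100  # inside frame 5 only (1060 < 1152)
        truth = frame_truth(
            [(sample / 256, (sample + 1) / 256)], times, self.CFG
        )
        assert truth[5]
        assert truth.sum() == 1

    def test_event_straddling_frame_boundary_hits_both(self):
        times = self._times(20)
        # 1-sample event at the first sample of frame 6 also lies in frame 5
        sample = 6 * 192
        truth = frame_truth(
            [(sample / 256, (sample + 1) / 256)], times, self.CFG
        )
        assert truth[5] and truth[6]
        assert truth.sum() == 2

    def test_empty_events_all_negative(self):
        assert not frame_truth([], self._times(10), self.CFG).any()


class TestEventCapture:
    CFG = FrameConfig()

    def test_constructed_coincidence_fractions(self):
        times = np.arange(30) * 192
        # three 10-frame events
        events = [
            (0.0, 10 * 192 / 256),
            (10 * 192 / 256, 20 * 192 / 256),
            (20 * 192 / 256, 30 * 192 / 256),
        ]
        flags = np.zeros((2, 30), dtype=bool)
        flags[:, 2] = True        # event 1: both channels
        flags[0, 12] = True       # event 2: one channel
        captured, total, coincidence = event_capture(
            flags, events, times, self.CFG
        )
        assert (captured, total) == (2, 3)
        assert coincidence == [1.0, 0.5, 0.0]

    def test_capture_monotone_in_flags(self, rng):
        times = np.arange(50) * 192
        events = [(5.0, 8.0), (20.0, 22.0)]
        flags = rng.random((3, 50)) < 0.05
        more = flags | (rng.random((3, 50)) < 0.1)
        c1, _, co1 = event_capture(flags, events, times, self.CFG)
        c2, _, co2 = event_capture(more, events, times, self.CFG)
        assert c2 >= c1
        assert all(b >= a for a, b in zip(co1, co2))

    def test_min_channel_combination_rule(self):
        flags = np.array(
            [[True, False, True], [False, False, True], [False, False, True]]
        )
        np.testing.assert_array_equal(
            combine_channel_flags(flags, 1), [True, False, True]
        )
        np.testing.assert_array_equal(
            combine_channel_flags(flags, 3), [False, False, True]
        )
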