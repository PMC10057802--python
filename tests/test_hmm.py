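"""Penalized Viterbi, the state-hypothesis loop, and track labeling."""

import itertools

import numpy as np
import pytest

from eeganomaly import (
    HmmConfig,
    HmmModel,
    PenalizedHMMSegmenter,
    viterbi_segment,
    hypothesize_states,
    label_track,
)
from eeganomaly.hmm import path_cost


def brute_force_cost(seq, centroids, penalty):
    """Exhaustive minimum over all K^F labelings."""
    K, F = len(centroids), len(seq)
    return min(
        path_cost(seq, np.array(lab), centroids, penalty)
        for lab in itertools.product(range(K), repeat=F)
    )


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        seq = rng.normal(size=(30, 4))
        path = viterbi_segment(seq, HmmModel(seq.mean(0, keepdims=True)))
        assert (path == 0).all()

    def test_zero_penalty_is_nearest_centroid(self, rng):
        seq = rng.normal(size=(50, 3))
        cents = rng.normal(size=(4, 3))
        path = viterbi_segment(seq, HmmModel(cents), HmmConfig(penalty=0.0))
        d = ((seq[:, None, :] - cents[None]) ** 2).mean(axis=2)
        np.testing.assert_array_equal(path, d.argmin(axis=1))

    def test_matches_brute_force_on_small_instances(self, rng):
        for _ in range(100):
            F = int(rng.integers(1, 9))
            K = int(rng.integers(1, 4))
            D = int(rng.integers(1, 4))
            seq = rng.normal(size=(F, D))
            cents = rng.normal(size=(K, D))
            pen = float(rng.choice([0.0, 0.1, 0.5, 2.0]))
            path = viterbi_segment(seq, HmmModel(cents), HmmConfig(penalty=pen))
            assert path_cost(seq, path, cents, pen) == pytest.approx(
                brute_force_cost(seq, cents, pen), abs=1e-9
            )

    def test_transitions_monotone_in_penalty(self, rng):
        for _ in range(30):
            seq = rng.normal(size=(8, 2))
            cents = rng.normal(size=(3, 2))
            n_prev = None
            for pen in [0.0, 0.05, 0.2, 1.0, 5.0]:
                path = viterbi_segment(
                    seq, HmmModel(cents), HmmConfig(penalty=pen)
                )
                n_trans = int(np.count_nonzero(np.diff(path)))
                if n_prev is not None:
                    assert n_trans <= n_prev
                n_prev = n_trans

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            viterbi_segment(rng.normal(size=(5, 3)), HmmModel(np.zeros((2, 4))))


def _planted_sequence(seed, delta=6.0, noise=0.3, lens=None):
    r = np.random.default_rng(seed)
    D = 8
    cents = np.zeros((3, D))
    cents[1, 0] = delta
    cents[2, 1] = delta
    lens = lens if lens is not None else r.integers(40, 80, size=3)
    seq = np.concatenate(
        [cents[i] + noise * r.normal(size=(lens[i], D)) for i in range(3)]
    )
    return seq, np.cumsum(lens)[:2]


class TestHypothesisLoop:
    CFG = HmmConfig(penalty=2.0, min_frequency=20)

    def test_single_tight_cluster_keeps_one_state(self, rng):
        seq = 5.0 + 0.05 * rng.normal(size=(200, 6))
        model, path = hypothesize_states(seq, HmmConfig(penalty=2.0))
        assert model.n_states == 1
        assert (path == 0).all()

    def test_planted_three_regimes_recovered(self):
        seq, true_bounds = _planted_sequence(0)
        model, path = hypothesize_states(seq, self.CFG)
        assert model.n_states == 3
        bounds = np.flatnonzero(np.diff(path)) + 1
        assert len(bounds) == 2
        np.testing.assert_allclose(bounds, true_bounds, atol=1)

    def test_short_burst_below_min_frequency_is_pruned(self, rng):
        seq = 0.1 * rng.normal(size=(120, 5))
        seq[50:60] += 8.0  # 10-frame aberrant burst < min_frequency 20
        model, path = hypothesize_states(seq, HmmConfig(min_frequency=20, penalty=2.0))
        assert model.n_states == 1
        assert (path == 0).all()

    def test_every_surviving_state_claims_min_frequency_frames(self):
        seq, _ = _planted_sequence(5)
        model, path = hypothesize_states(seq, self.CFG)
        counts = np.bincount(path, minlength=model.n_states)
        assert (counts >= self.CFG.min_frequency).all()

    def test_deterministic_for_fixed_input(self):
        seq, _ = _planted_sequence(3)
        m1, p1 = hypothesize_states(seq, self.CFG)
        m2, p2 = hypothesize_states(seq, self.CFG)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_sequence_shorter_than_min_frequency_keeps_one_state(self, rng):
        seq = rng.normal(size=(10, 4))
        model, path = hypothesize_states(seq, HmmConfig(min_frequency=20))
        assert model.n_states == 1


class TestLabelTrack:
    def test_single_state_track_has_no_flags(self):
        model = HmmModel(np.zeros((1, 3)))
        track = label_track(np.zeros(50, dtype=int), model, np.ones(50))
        assert track.background_id == 0
        assert not track.flags.any()

    def test_minority_state_is_flagged(self):
        model = HmmModel(np.zeros((2, 3)))
        states = np.array([0] * 90 + [1] * 10)
        errors = np.concatenate([np.ones(90), 5 * np.ones(10)])
        track = label_track(states, model, errors)
        assert track.background_id == 0
        assert track.flags.sum() == 10
        assert track.state_mean_error == {0: 1.0, 1: 5.0}

    def test_flag_count_conservation(self, rng):
        model = HmmModel(np.zeros((3, 2)))
        states = rng.integers(0, 3, size=200)
        track = label_track(states, model, rng.random(200))
        bg_count = np.count_nonzero(states == track.background_id)
        assert track.flags.sum() == 200 - bg_count

    def test_error_ratio_policy_only_flags_hot_states(self):
        model = HmmModel(np.zeros((3, 2)))
        states = np.array([0] * 80 + [1] * 10 + [2] * 10)
        errors = np.concatenate([np.ones(80), 1.2 * np.ones(10), 9 * np.ones(10)])
        track = label_track(states, model, errors, flag_policy="error_ratio")
        assert track.flags.sum() == 10  # state 1 is below 2x background
        assert track.flags[-10:].all()


class TestSegmenterEstimator:
    def test_fit_predict_round_trip(self):
        seq, _ = _planted_sequence(1)
        seg = PenalizedHMMSegmenter(penalty=2.0, min_frequency=20)
        labels = seg.fit_predict(seq)
        assert seg.n_states_ == 3
        np.testing.assert_array_equal(seg.predict(seq), labels)
        assert seg.background_id_ == np.argmax(np.bincount(labels))

    def test_get_params_round_trip(self):
        seg = PenalizedHMMSegmenter(penalty=7.0)
        assert PenalizedHMMSegmenter(**seg.get_params()).penalty == 7.0
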