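"""Penalized-Viterbi segmentation with a generative state-hypothesis loop.

The temporal model is deliberately spartan: states are centroid vectors in
the frame-feature space (here, autoencoder error vectors), the emission
cost of assigning frame x to state k is the mean squared deviation
``mean((x − c_k)²)``, and every change of state along the path costs a
fixed ``penalty``.  The exact dynamic program (penalized Viterbi)
minimizes

    Σ_t  emission(x_t, s_t)  +  penalty · #{t : s_t ≠ s_{t−1}}

which yields piecewise-constant segmentations whose minimum segment
"value" is controlled by the penalty.

States are not fixed in advance.  A generative loop hypothesizes them from
the data: starting from a single state at the global centroid, it
repeatedly (1) Viterbi-segments, (2) re-estimates centroids from claimed
frames, (3) proposes a new state from the contiguous stretch of frames
worst explained by the current model, and (4) prunes any state claiming
fewer than ``min_frequency`` frames.  A proposal is kept only if it lowers
the total path cost, so the loop terminates deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "HmmConfig",
    "HmmModel",
    "StateTrack",
    "PenalizedHMMSegmenter",
    "viterbi_segment",
    "hypothesize_states",
    "label_track",
    "path_cost",
]


@dataclass(frozen=True)
class HmmConfig:
    """Segmenter parameters.

    penalty : additive path cost per state transition (same units as the
        mean-squared emission cost).
    min_frequency : minimum number of frames a state must claim to
        survive pruning.
    max_iterations : cap on state-hypothesis proposals.
    """

    penalty: float = 200.0
    min_frequency: int = 20
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.min_frequency < 1:
            raise ValueError("min_frequency must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class HmmModel:
    """Surviving states: one centroid row per state id."""

    centroids: np.ndarray  # (K, D)

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, float))
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")

    @property
    def n_states(self) -> int:
        return self.centroids.shape[0]


@dataclass
class StateTrack:
    """Per-frame state ids for one channel, with the anomaly calls."""

    states: np.ndarray  # (F,) int
    state_mean_error: dict[int, float]
    background_id: int
    flags: np.ndarray  # (F,) bool
    scalar_error: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _emission_costs(seq: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(F, K) mean squared deviation, via the expanded quadratic."""
    x2 = np.einsum("fd,fd->f", seq, seq)
    c2 = np.einsum("kd,kd->k", centroids, centroids)
    cost = (x2[:, None] - 2.0 * seq @ centroids.T + c2[None, :]) / seq.shape[1]
    return np.maximum(cost, 0.0)


def viterbi_segment(
    seq: np.ndarray, model: HmmModel | np.ndarray, cfg: HmmConfig | None = None
) -> np.ndarray:
    """Exact minimum-cost state path under the transition penalty.

    Ties are broken toward the lower state id (both for predecessors and
    for the final state), which in particular favors staying in the
    current state's run when it is among the minimizers; the result is
    platform-independent.  With penalty 0 this reduces to per-frame
    nearest-centroid assignment.
    """
    cfg = cfg or HmmConfig()
    centroids = model.centroids if isinstance(model, HmmModel) else np.atleast_2d(model)
    seq = np.atleast_2d(np.asarray(seq, dtype=np.float64))
    if seq.shape[0] < 1:
        raise ValueError("need at least one frame")
    if seq.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"frame dimension {seq.shape[1]} != centroid dimension "
            f"{centroids.shape[1]}"
        )
    emis = _emission_costs(seq, centroids)
    F, K = emis.shape
    back = np.empty((F, K), dtype=np.intp)
    cost = emis[0].copy()
    back[0] = np.arange(K)
    for t in range(1, F):
        j_best = int(np.argmin(cost))  # lowest index among minimizers
        switch = cost[j_best] + cfg.penalty
        stay = cost
        # predecessor per target state k: lower id wins ties
        take_switch = (switch < stay) | ((switch == stay) & (j_best < np.arange(K)))
        prev = np.where(take_switch, j_best, np.arange(K))
        cost = np.where(take_switch, switch, stay) + emis[t]
        back[t] = prev
    path = np.empty(F, dtype=np.intp)
    path[-1] = int(np.argmin(cost))
    for t in range(F - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_cost(
    seq: np.ndarray, path: np.ndarray, centroids: np.ndarray, penalty: float
) -> float:
    """Total emission + transition cost of a given labeling."""
    seq = np.atleast_2d(seq)
    emis = _emission_costs(seq, np.atleast_2d(centroids))
    e = float(emis[np.arange(len(path)), path].sum())
    return e + penalty * int(np.count_nonzero(np.diff(path)))


def _runs(path: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) spans of constant state."""
    if len(path) == 0:
        return []
    cuts = np.flatnonzero(np.diff(path)) + 1
    bounds = np.concatenate([[0], cuts, [len(path)]])
    return list(zip(bounds[:-1], bounds[1:]))


def _refine(
    seq: np.ndarray, centroids: np.ndarray, cfg: HmmConfig, max_passes: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate Viterbi / centroid re-estimation / pruning to a fixed point.

    States claiming fewer than ``min_frequency`` frames are dropped (their
    frames are reassigned on the next Viterbi pass); at least one state
    always survives, so sequences shorter than ``min_frequency`` keep the
    single global state.
    """
    for _ in range(max_passes):
        path = viterbi_segment(seq, HmmModel(centroids), cfg)
        counts = np.bincount(path, minlength=centroids.shape[0])
        new = centroids.copy()
        for k in np.flatnonzero(counts):
            new[k] = seq[path == k].mean(axis=0)
        keep = counts >= cfg.min_frequency
        if not keep.any():
            keep[int(np.argmax(counts))] = True
        pruned = not keep.all()
        moved = not np.allclose(new[keep], centroids[keep], rtol=0, atol=1e-12)
        centroids = new[keep]
        if not pruned and not moved:
            break
    path = viterbi_segment(seq, HmmModel(centroids), cfg)
    return centroids, path


def hypothesize_states(
    seq: np.ndarray, cfg: HmmConfig | None = None
) -> tuple[HmmModel, np.ndarray]:
    """Generative state-hypothesis loop; deterministic for fixed input.

    New states are proposed from the contiguous window of
    ``min_frequency`` frames with the highest mean emission cost under the
    current segmentation — the stretch the model explains worst and the
    shortest stretch that could sustain a surviving state.  A proposal is
    accepted only if the refined segmentation lowers the total path cost.
    """
    cfg = cfg or HmmConfig()
    seq = np.atleast_2d(np.asarray(seq, dtype=np.float64))
    if seq.shape[0] < 1:
        raise ValueError("need at least one frame")
    centroids = seq.mean(axis=0, keepdims=True)
    centroids, path = _refine(seq, centroids, cfg)
    best = path_cost(seq, path, centroids, cfg.penalty)

    F = seq.shape[0]
    win = min(cfg.min_frequency, F)
    for _ in range(cfg.max_iterations):
        emis = _emission_costs(seq, centroids)
        per_frame = emis[np.arange(F), path]
        # highest-mean window of length `win` (sliding sum, first on ties)
        csum = np.concatenate([[0.0], np.cumsum(per_frame)])
        window_means = (csum[win:] - csum[:-win]) / win
        lo = int(np.argmax(window_means))
        candidate = seq[lo : lo + win].mean(axis=0)
        trial_cents, trial_path = _refine(
            seq, np.vstack([centroids, candidate]), cfg
        )
        trial = path_cost(seq, trial_path, trial_cents, cfg.penalty)
        if trial < best - 1e-9 * (1.0 + abs(best)):
            centroids, path, best = trial_cents, trial_path, trial
        else:
            break
    return HmmModel(centroids), path


def label_track(
    seq_states: np.ndarray,
    model: HmmModel,
    scalar_errors: np.ndarray,
    flag_policy: str = "nonmodal",
    error_ratio: float = 2.0,
) -> StateTrack:
    """Turn a state path into anomaly calls.

    The background state is the modal (most frequent) state — normal
    activity dominates by assumption.  Under the default ``"nonmodal"``
    policy every frame in any other state is flagged; under
    ``"error_ratio"`` only states whose mean scalar reconstruction error
    exceeds the background's by ``error_ratio`` are flagged.
    """
    seq_states = np.asarray(seq_states, dtype=np.intp)
    scalar_errors = np.asarray(scalar_errors, dtype=np.float64)
    if seq_states.shape != scalar_errors.shape:
        raise ValueError("state path and scalar errors differ in length")
    counts = np.bincount(seq_states, minlength=model.n_states)
    background = int(np.argmax(counts))
    mean_err = {
        int(k): float(scalar_errors[seq_states == k].mean())
        for k in range(model.n_states)
        if counts[k] > 0
    }
    if flag_policy == "nonmodal":
        flags = seq_states != background
    elif flag_policy == "error_ratio":
        bg = mean_err.get(background, 0.0)
        hot = {
            k for k, e in mean_err.items() if k != background and e > error_ratio * bg
        }
        flags = np.isin(seq_states, list(hot))
    else:
        raise ValueError(f"unknown flag_policy {flag_policy!r}")
    return StateTrack(
        states=seq_states,
        state_mean_error=mean_err,
        background_id=background,
        flags=flags,
        scalar_error=scalar_errors,
    )


class PenalizedHMMSegmenter(ClusterMixin, BaseEstimator):
    """Estimator wrapper: hypothesize states on fit, Viterbi on predict.

    Parameters mirror :class:`HmmConfig`.  ``fit(X)`` runs the hypothesis
    loop on the (F, D) frame sequence; ``labels_`` is the training path,
    ``centroids_`` the surviving states, ``background_id_`` the modal
    state.  ``predict(X)`` Viterbi-decodes a new sequence against the
    fitted states.
    """

    def __init__(
        self,
        penalty: float = 200.0,
        min_frequency: int = 20,
        max_iterations: int = 20,
    ):
        self.penalty = penalty
        self.min_frequency = min_frequency
        self.max_iterations = max_iterations

    def _config(self) -> HmmConfig:
        return HmmConfig(self.penalty, self.min_frequency, self.max_iterations)

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        model, path = hypothesize_states(X, self._config())
        self.centroids_ = model.centroids
        self.n_states_ = model.n_states
        self.labels_ = path
        counts = np.bincount(path, minlength=model.n_states)
        self.background_id_ = int(np.argmax(counts))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        return viterbi_segment(X, HmmModel(self.centroids_), self._config())

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
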