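"""Frame-level and event-level evaluation against seizure annotations.

Frame truth uses the most permissive overlap rule: a frame is positive if
its sample interval overlaps an annotated event by at least one sample.
Because events only partially overlap fixed-size frames, per-frame
sensitivity is a lower bound on practical detection performance, so
event-level capture (any flagged frame, any channel, inside the event)
and channel coincidence (fraction of channels flagging the event) are
reported alongside the 2×2-derived metrics.

Any metric whose denominator is zero is reported as ``None``
("undefined"), never silently as 0 or NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .spectral import FrameConfig

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "frame_truth",
    "confusion",
    "compute_metrics",
    "event_capture",
    "combine_channel_flags",
    "micro_average",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Frame-level 2×2 counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    """The eleven standard binary-classification metrics.

    sensitivity (recall), specificity, accuracy, f1, ppv (precision),
    npv, fpr, fnr, fdr, fomr (false omission rate) and mcc (Matthews
    correlation).  ``None`` marks an undefined value.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    ppv: float | None
    npv: float | None
    fpr: float | None
    fnr: float | None
    fdr: float | None
    fomr: float | None
    mcc: float | None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        if self.counts is not None:
            d["counts"] = asdict(self.counts)
        return d


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """All eleven metrics from the counts; zero denominators → ``None``."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (
        (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den > 0 else None
    )
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=_ratio(tp + tn, c.total),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        ppv=ppv,
        npv=npv,
        fpr=None if spec is None else 1.0 - spec,
        fnr=None if sens is None else 1.0 - sens,
        fdr=None if ppv is None else 1.0 - ppv,
        fomr=None if npv is None else 1.0 - npv,
        mcc=mcc,
        counts=c,
    )


def _event_sample_interval(
    start_s: float, end_s: float, sample_rate: int
) -> tuple[float, float]:
    return start_s * sample_rate, end_s * sample_rate


def frame_truth(
    events: list[tuple[float, float]],
    frame_times: np.ndarray,
    cfg: FrameConfig | None = None,
    sample_rate: int = 256,
) -> np.ndarray:
    """Per-frame boolean truth under the ≥1-sample overlap rule.

    ``events`` is a list of (start_seconds, end_seconds); a frame starting
    at sample s is positive iff [s, s + window_len) intersects any event's
    sample interval.
    """
    cfg = cfg or FrameConfig()
    frame_times = np.asarray(frame_times)
    truth = np.zeros(len(frame_times), dtype=bool)
    f_lo = frame_times.astype(np.float64)
    f_hi = f_lo + cfg.window_len
    for start_s, end_s in events:
        e_lo, e_hi = _event_sample_interval(start_s, end_s, sample_rate)
        truth |= (f_lo < e_hi) & (f_hi > e_lo)
    return truth


def confusion(flags: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Standard 2×2 tally of predicted flags against truth."""
    flags = np.asarray(flags, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if flags.shape != truth.shape:
        raise ValueError(
            f"flags length {flags.shape} != truth length {truth.shape}"
        )
    return ConfusionCounts(
        tp=int(np.count_nonzero(flags & truth)),
        fp=int(np.count_nonzero(flags & ~truth)),
        tn=int(np.count_nonzero(~flags & ~truth)),
        fn=int(np.count_nonzero(~flags & truth)),
    )


def combine_channel_flags(
    channel_flags: np.ndarray, min_channels: int = 1
) -> np.ndarray:
    """Global frame flag: flagged in at least ``min_channels`` channels."""
    channel_flags = np.atleast_2d(np.asarray(channel_flags, dtype=bool))
    return channel_flags.sum(axis=0) >= min_channels


def event_capture(
    channel_flags: np.ndarray,
    events: list[tuple[float, float]],
    frame_times: np.ndarray,
    cfg: FrameConfig | None = None,
    sample_rate: int = 256,
) -> tuple[int, int, list[float]]:
    """Event-level capture and channel coincidence.

    An event is captured iff at least one of its truth-positive frames is
    flagged in at least one channel.  Its coincidence is the fraction of
    channels with ≥1 flagged frame inside the event.  Returns
    (captured, total, per-event coincidence fractions).
    """
    cfg = cfg or FrameConfig()
    channel_flags = np.atleast_2d(np.asarray(channel_flags, dtype=bool))
    n_channels = channel_flags.shape[0]
    captured = 0
    coincidence: list[float] = []
    for start_s, end_s in events:
        mask = frame_truth([(start_s, end_s)], frame_times, cfg, sample_rate)
        hit_channels = int(
            np.count_nonzero(channel_flags[:, mask].any(axis=1))
        )
        coincidence.append(hit_channels / n_channels)
        if hit_channels > 0:
            captured += 1
    return captured, len(events), coincidence


def micro_average(counts: list[ConfusionCounts]) -> MetricsReport:
    """Metrics of the summed confusion counts (micro-averaging)."""
    total = ConfusionCounts()
    for c in counts:
        total = total + c
    return compute_metrics(total)
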