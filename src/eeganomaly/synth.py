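"""Synthetic multichannel EEG with planted rhythmic discharge events.

The generator emulates the statistics that matter to the detector, not
scalp physics: background activity is a per-channel mixture of an alpha
(8–12 Hz) and a theta (4–7 Hz) oscillation with random phases plus white
Gaussian noise, and rare high-amplitude events are planted as ~3 Hz
spike-and-wave discharges — each cycle a slow wave plus a sharp transient,
so the event spectrum is a 3 Hz fundamental with harmonics, distinctly
broadband against the narrowband background.  Event onsets/offsets fall
on whole seconds so the matching CHB-MIT-style annotation summary
round-trips exactly.

What this does not emulate: volume conduction and inter-channel
correlation structure, eye-blink/EMG artifacts, electrode pops, or
non-stationary background (sleep stages).  Detection results on these
fixtures demonstrate the mechanism, not clinical performance.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Recording, AnnotationSet, write_edf

__all__ = ["SynthConfig", "generate", "write_fixture"]

# standard bipolar longitudinal labels to cycle through
_BIPOLAR_LABELS = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "T7-FT9", "FT9-FT10",
    "FT10-T8", "P7-T7", "C4-T8", "CZ-C4",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic recording.

    Background amplitudes are in microvolts: 30 µV alpha, 20 µV theta,
    10 µV Gaussian noise — a background RMS near 27 µV, ordinary awake
    scalp EEG scale.  Events are scaled so their RMS is
    ``amplitude_ratio`` times the channel's background RMS.
    """

    n_channels: int = 8
    duration_s: int = 600
    sample_rate: int = 256
    alpha_amp: float = 30.0
    theta_amp: float = 20.0
    noise_sigma: float = 10.0
    n_events: int = 3
    event_duration_range: tuple[float, float] = (10.0, 60.0)
    event_freq: float = 3.0
    amplitude_ratio: float = 4.0
    channel_subset: float = 1.0
    margin_s: int = 10
    seed: int = 0
    file_id: str = ""

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.duration_s < 1:
            raise ValueError("need >= 1 channel and >= 1 s duration")
        lo, hi = self.event_duration_range
        if not 0 < lo <= hi:
            raise ValueError("bad event_duration_range")
        if self.amplitude_ratio < 3.0:
            raise ValueError("amplitude_ratio must be >= 3")
        if not 0.0 < self.channel_subset <= 1.0:
            raise ValueError("channel_subset must be in (0, 1]")


def _spike_wave(t: np.ndarray, freq: float) -> np.ndarray:
    """Unit-RMS spike-and-wave template: slow sine + a sharp Gaussian
    transient once per cycle."""
    phase = (t * freq) % 1.0
    slow = np.sin(2 * np.pi * t * freq)
    spike = np.exp(-0.5 * ((phase - 0.15) / 0.03) ** 2)
    wave = slow + 2.5 * spike
    return wave / np.sqrt(np.mean(wave**2))


def _place_events(cfg: SynthConfig, rng: np.random.Generator):
    """Non-overlapping whole-second event intervals with margins.

    Total event time is capped at 20% of the recording; durations are
    re-drawn (deterministically) until the cap holds.
    """
    lo, hi = cfg.event_duration_range
    lo_i, hi_i = int(np.ceil(lo)), int(np.floor(hi))
    budget = 0.2 * cfg.duration_s
    if cfg.n_events * lo_i > budget:
        raise ValueError(
            f"{cfg.n_events} events of >= {lo_i} s exceed 20% of a "
            f"{cfg.duration_s} s recording"
        )
    for _ in range(1000):
        durs = rng.integers(lo_i, hi_i + 1, size=cfg.n_events)
        if durs.sum() <= budget:
            break
    else:
        raise ValueError("could not draw event durations within the 20% cap")

    needed = durs.sum() + (cfg.n_events + 1) * cfg.margin_s
    if needed > cfg.duration_s:
        raise ValueError(
            f"cannot place {cfg.n_events} events totalling {durs.sum()} s "
            f"with {cfg.margin_s} s margins in {cfg.duration_s} s"
        )
    # distribute the slack among the n_events+1 gaps
    slack = cfg.duration_s - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=cfg.n_events))
    gaps = np.diff(np.concatenate([[0], cuts])) + cfg.margin_s
    starts, pos = [], 0
    for g, d in zip(gaps, durs):
        pos += int(g)
        starts.append(pos)
        pos += int(d)
    return [(int(s), int(s + d)) for s, d in zip(starts, durs)]


def generate(cfg: SynthConfig) -> tuple[Recording, AnnotationSet]:
    """Deterministic (under ``cfg.seed``) recording + annotations."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.duration_s * cfg.sample_rate
    t = np.arange(n) / cfg.sample_rate

    intervals = _place_events(cfg, rng) if cfg.n_events else []

    signals = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        f_alpha = rng.uniform(8.0, 12.0)
        f_theta = rng.uniform(4.0, 7.0)
        ph_a, ph_t = rng.uniform(0, 2 * np.pi, size=2)
        signals[ch] = (
            cfg.alpha_amp * np.sin(2 * np.pi * f_alpha * t + ph_a)
            + cfg.theta_amp * np.sin(2 * np.pi * f_theta * t + ph_t)
            + rng.normal(0.0, cfg.noise_sigma, size=n)
        )

    bg_rms = float(np.sqrt(np.mean(signals**2)))
    n_express = max(1, int(round(cfg.channel_subset * cfg.n_channels)))
    for start_s, end_s in intervals:
        sl = slice(start_s * cfg.sample_rate, end_s * cfg.sample_rate)
        chans = (
            np.arange(cfg.n_channels)
            if n_express == cfg.n_channels
            else np.sort(
                rng.choice(cfg.n_channels, size=n_express, replace=False)
            )
        )
        burst = cfg.amplitude_ratio * bg_rms * _spike_wave(t[sl], cfg.event_freq)
        for ch in chans:
            signals[ch, sl] += burst

    file_id = cfg.file_id or f"synth{cfg.seed:03d}"
    rec = Recording(
        channel_labels=[
            _BIPOLAR_LABELS[i % len(_BIPOLAR_LABELS)]
            for i in range(cfg.n_channels)
        ],
        sample_rate=cfg.sample_rate,
        signals=signals,
        start_time=_dt.datetime(2000, 1, 1, 0, 0, 0),
        file_id=file_id,
    )
    ann = AnnotationSet(
        events=[(file_id, float(s), float(e)) for s, e in intervals],
        total_files=1,
        file_durations={file_id: float(cfg.duration_s)},
    )
    return rec, ann


def _hms(seconds: int) -> str:
    return str(_dt.timedelta(seconds=int(seconds)))[-8:].rjust(8, "0")


def write_fixture(
    rec: Recording, ann: AnnotationSet, directory: str | Path
) -> tuple[Path, Path]:
    """Write the EDF and a CHB-MIT-dialect summary; returns both paths.

    The summary round-trips through
    :func:`~eeganomaly.io.parse_annotation_summary`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edf_path = directory / f"{rec.file_id}.edf"
    write_edf(rec, edf_path)

    events = ann.events_for(rec.file_id)
    lines = [
        f"Data Sampling Rate: {rec.sample_rate} Hz",
        "",
        f"File Name: {rec.file_id}.edf",
        "File Start Time: 00:00:00",
        f"File End Time: {_hms(int(round(rec.duration_s)))}",
        f"Number of Seizures in File: {len(events)}",
    ]
    for i, (s, e) in enumerate(events, start=1):
        tag = f"Seizure {i} " if len(events) > 1 else "Seizure "
        lines.append(f"{tag}Start Time: {int(s)} seconds")
        lines.append(f"{tag}End Time: {int(e)} seconds")
    summary_path = directory / f"{rec.file_id}-summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    return edf_path, summary_path
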