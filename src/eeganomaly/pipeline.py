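"""End-to-end orchestration: recording → spectra → errors → state tracks.

Each channel flows through featurize → autoencoder fit → reconstruction
error → state hypothesis → anomaly flags, entirely independently of the
other channels, so results are identical regardless of execution order or
worker count; per-channel seeds are derived from the run seed and the
channel index, never from scheduling.  Memory stays bounded per
recording: complexity is O(T) per channel times O(N) channels.
"""

from __future__ import annotations

import fnmatch
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
from joblib import Parallel, delayed

from .io import Recording, AnnotationSet, read_edf, parse_annotation_summary
from .spectral import FrameConfig, featurize
from .autoencoder import FrameAutoencoder
from .hmm import HmmConfig, HmmModel, hypothesize_states, label_track, StateTrack
from .evaluation import (
    frame_truth,
    confusion,
    compute_metrics,
    combine_channel_flags,
    event_capture,
    micro_average,
    ConfusionCounts,
)

log = logging.getLogger("eeganomaly")

__all__ = ["RunConfig", "ChannelResult", "RunResult", "run_recording", "run_batch"]


@dataclass
class RunConfig:
    """Every knob of one pipeline run; the manifest serializes it all."""

    # windowing
    window_len: int = 256
    overlap: int = 64
    taper: str | None = None
    # autoencoder
    hidden_dim: int = 64
    negative_slope: float = 0.01
    learning_rate: float = 0.001
    epochs: int = 25
    batch_size: int | None = 16
    optimizer: str = "adam"
    normalize_input: bool = True
    pool_channels: bool = False
    # segmenter
    penalty: float = 200.0
    min_frequency: int = 20
    max_iterations: int = 20
    hmm_input: str = "error_vec"  # error_vec | error_scalar | spectrum
    flag_policy: str = "nonmodal"  # nonmodal | error_ratio
    error_ratio: float = 2.0
    # evaluation
    min_channels: int = 1
    # execution
    seed: int = 0
    workers: int = 1
    include_channels: list[str] = field(default_factory=list)
    exclude_channels: list[str] = field(default_factory=list)

    def frame_config(self) -> FrameConfig:
        return FrameConfig(self.window_len, self.overlap, self.taper)

    def hmm_config(self) -> HmmConfig:
        return HmmConfig(self.penalty, self.min_frequency, self.max_iterations)

    def channel_seed(self, channel_index: int) -> int:
        # stable under channel order and worker scheduling
        return int((self.seed * 1_000_003 + channel_index) % (2**31 - 1))


@dataclass
class ChannelResult:
    label: str
    model: FrameAutoencoder
    states: HmmModel
    track: StateTrack


@dataclass
class RunResult:
    file_id: str
    channel_labels: list[str]
    frame_times: np.ndarray
    channels: list[ChannelResult]
    config: RunConfig
    sample_rate: int

    @property
    def flags(self) -> np.ndarray:
        """(n_channels, F) per-channel anomaly flags."""
        return np.array([c.track.flags for c in self.channels])


def _select_channels(rec: Recording, cfg: RunConfig) -> list[int]:
    keep = []
    for i, label in enumerate(rec.channel_labels):
        if cfg.include_channels and not any(
            fnmatch.fnmatch(label, p) for p in cfg.include_channels
        ):
            continue
        if any(fnmatch.fnmatch(label, p) for p in cfg.exclude_channels):
            continue
        keep.append(i)
    if not keep:
        raise ValueError("channel filters removed every channel")
    return keep


def _process_channel(
    spectra: np.ndarray,
    label: str,
    cfg: RunConfig,
    seed: int,
    pooled_model: FrameAutoencoder | None = None,
) -> ChannelResult:
    if pooled_model is None:
        model = FrameAutoencoder(
            hidden_dim=cfg.hidden_dim,
            negative_slope=cfg.negative_slope,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            optimizer=cfg.optimizer,
            normalize_input=cfg.normalize_input,
            random_state=seed,
        ).fit(spectra)
    else:
        model = pooled_model
    err_vec = model.transform(spectra)
    scalar = err_vec.mean(axis=-1)
    if cfg.hmm_input == "error_vec":
        hmm_in = err_vec
    elif cfg.hmm_input == "error_scalar":
        hmm_in = scalar[:, None]
    elif cfg.hmm_input == "spectrum":
        hmm_in = spectra
    else:
        raise ValueError(f"unknown hmm_input {cfg.hmm_input!r}")
    states, path = hypothesize_states(hmm_in, cfg.hmm_config())
    track = label_track(
        path, states, scalar, cfg.flag_policy, cfg.error_ratio
    )
    return ChannelResult(label=label, model=model, states=states, track=track)


def run_recording(
    rec: Recording | str | Path,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
    annotations: AnnotationSet | str | Path | None = None,
) -> RunResult:
    """Run the full per-channel pipeline on one recording.

    If ``out_dir`` is given, writes the state-track TSV, per-channel model
    HDF5, a reproducibility manifest, and (when annotations are supplied)
    a metrics JSON.
    """
    cfg = cfg or RunConfig()
    if not isinstance(rec, Recording):
        rec = read_edf(rec)
    if annotations is not None and not isinstance(annotations, AnnotationSet):
        annotations = parse_annotation_summary(annotations)

    keep = _select_channels(rec, cfg)
    spectra = featurize(rec, cfg.frame_config())
    log.info(
        "%s: %d channels, %d frames", rec.file_id, len(keep), spectra.n_frames
    )
    if spectra.n_frames == 0:
        raise ValueError(
            f"{rec.file_id}: recording shorter than one window"
        )

    pooled = None
    if cfg.pool_channels:
        stacked = spectra.frames[keep].reshape(-1, cfg.window_len)
        pooled = FrameAutoencoder(
            hidden_dim=cfg.hidden_dim,
            negative_slope=cfg.negative_slope,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            optimizer=cfg.optimizer,
            normalize_input=cfg.normalize_input,
            random_state=cfg.channel_seed(0),
        ).fit(stacked)

    tasks = [
        (i, spectra.frames[i], rec.channel_labels[i]) for i in keep
    ]
    if cfg.workers == 1:
        channels = [
            _process_channel(f, lbl, cfg, cfg.channel_seed(i), pooled)
            for i, f, lbl in tasks
        ]
    else:
        channels = Parallel(n_jobs=cfg.workers)(
            delayed(_process_channel)(
                f, lbl, cfg, cfg.channel_seed(i), pooled
            )
            for i, f, lbl in tasks
        )

    result = RunResult(
        file_id=rec.file_id,
        channel_labels=[rec.channel_labels[i] for i in keep],
        frame_times=spectra.frame_times,
        channels=channels,
        config=cfg,
        sample_rate=rec.sample_rate,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), annotations)
    return result


def _write_track_tsv(result: RunResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "channel\tframe_index\tstart_sample\tstate_id\tscalar_error\tflag\n"
        )
        for ch in result.channels:
            for j, t0 in enumerate(result.frame_times):
                fh.write(
                    f"{ch.label}\t{j}\t{int(t0)}\t{int(ch.track.states[j])}\t"
                    f"{ch.track.scalar_error[j]:.9g}\t"
                    f"{int(ch.track.flags[j])}\n"
                )


def evaluate_run(
    result: RunResult, annotations: AnnotationSet
) -> dict:
    """Frame- and event-level metrics for one completed run."""
    cfg = result.config
    fcfg = cfg.frame_config()
    events = annotations.events_for(result.file_id)
    truth = frame_truth(
        events, result.frame_times, fcfg, result.sample_rate
    )
    flags = combine_channel_flags(result.flags, cfg.min_channels)
    counts = confusion(flags, truth)
    captured, total, coincidence = event_capture(
        result.flags, events, result.frame_times, fcfg, result.sample_rate
    )
    report = compute_metrics(counts).as_dict()
    report["event_capture"] = {"captured": captured, "total": total}
    report["coincidence"] = coincidence
    return report


def _write_bundle(
    result: RunResult, out_dir: Path, annotations: AnnotationSet | None
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    base = out_dir / result.file_id
    _write_track_tsv(result, base.with_suffix(".track.tsv"))
    with h5py.File(base.with_suffix(".models.h5"), "w") as h:
        for ch in result.channels:
            grp = h.create_group(ch.label.replace("/", "_"))
            ch.model.save(grp)
            grp.create_dataset("state_centroids", data=ch.states.centroids)
    from . import __version__ as version

    manifest = {
        "file_id": result.file_id,
        "software_version": version,
        "channels": result.channel_labels,
        "n_frames": int(len(result.frame_times)),
        "sample_rate": result.sample_rate,
        "config": asdict(result.config),
    }
    with open(base.with_suffix(".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if annotations is not None:
        with open(base.with_suffix(".metrics.json"), "w") as fh:
            json.dump(evaluate_run(result, annotations), fh, indent=2)


def run_batch(
    directory: str | Path,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
    annotations: AnnotationSet | str | Path | None = None,
) -> dict:
    """Process every EDF in a directory; files stream one at a time.

    Per-file failures are recorded and the batch continues.  Returns an
    aggregate report with micro-averaged metrics (summed confusion
    counts) when annotations are available.
    """
    cfg = cfg or RunConfig()
    directory = Path(directory)
    paths = sorted(directory.glob("*.edf"))
    if not paths:
        raise ValueError(f"no EDF files in {directory}")
    if annotations is not None and not isinstance(annotations, AnnotationSet):
        annotations = parse_annotation_summary(annotations)

    per_file: dict[str, dict] = {}
    failures: dict[str, str] = {}
    counts: list[ConfusionCounts] = []
    captured_total = [0, 0]
    for path in paths:
        try:
            result = run_recording(path, cfg, out_dir, annotations)
        except Exception as exc:  # noqa: BLE001 - batch isolation
            log.error("%s failed: %s", path.name, exc)
            failures[path.stem] = str(exc)
            continue
        if annotations is not None:
            report = evaluate_run(result, annotations)
            per_file[result.file_id] = report
            c = report["counts"]
            counts.append(ConfusionCounts(**c))
            captured_total[0] += report["event_capture"]["captured"]
            captured_total[1] += report["event_capture"]["total"]
        else:
            per_file[result.file_id] = {"n_frames": len(result.frame_times)}

    aggregate: dict = {
        "n_files": len(paths),
        "n_processed": len(per_file),
        "failures": failures,
        "per_file": per_file,
    }
    if annotations is not None and counts:
        agg = micro_average(counts).as_dict()
        agg["event_capture"] = {
            "captured": captured_total[0],
            "total": captured_total[1],
        }
        aggregate["overall"] = agg
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "batch_report.json", "w") as fh:
            json.dump(aggregate, fh, indent=2, sort_keys=True)
    return aggregate
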