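"""EDF (European Data Format) recordings and seizure-annotation summaries.

EDF stores multichannel biosignals as 16-bit integers with a per-channel
affine map between digital and physical units.  The codec here implements
the plain 16-bit EDF layout (256-byte fixed header, 256 bytes per signal
header, little-endian int16 data records); EDF+ annotation streams and BDF
are out of scope.  Annotation summaries follow the plain-text dialect used
by the CHB-MIT scalp-EEG corpus ("File Name:", "Number of Seizures in
File:", "Seizure [k ]Start/End Time: <n> seconds").
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "AnnotationSet",
    "EdfParseError",
    "read_edf",
    "write_edf",
    "parse_annotation_summary",
]

_EDF_HEADER_LEN = 256
_EDF_SIGNAL_HEADER_LEN = 256


class EdfParseError(ValueError):
    """Raised when an EDF header or annotation summary cannot be parsed."""


@dataclass
class Recording:
    """A multichannel signal in microvolts.

    Attributes
    ----------
    channel_labels : list of str
        One label per channel, preserved verbatim (e.g. ``"FP1-F7"``).
    sample_rate : int
        Samples per second, shared by all channels.
    signals : ndarray, shape (n_channels, n_samples)
        Physical values in microvolts.
    start_time : datetime or None
        Recording start, if the file declares one.
    file_id : str
        Identifier used to match annotations (file stem by convention).
    """

    channel_labels: list[str]
    sample_rate: int
    signals: np.ndarray
    start_time: _dt.datetime | None = None
    file_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (n_channels, n_samples)")
        if self.signals.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.signals.shape[0] < 1 or self.signals.shape[1] < 1:
            raise ValueError("need at least one channel and one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class AnnotationSet:
    """Seizure events parsed from a summary file.

    ``events`` holds ``(file_id, start_seconds, end_seconds)`` triples with
    ``0 <= start < end``; ``file_durations`` maps file_id to duration in
    seconds where the summary declares start/end clock times.
    """

    events: list[tuple[str, float, float]] = field(default_factory=list)
    total_files: int = 0
    file_durations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, start, end in self.events:
            if start < 0 or end <= start:
                raise ValueError(f"bad event ({fid}, {start}, {end})")

    def events_for(self, file_id: str) -> list[tuple[float, float]]:
        """Events for one file, matched on the stem, case-insensitively."""
        key = _stem(file_id).lower()
        return [
            (s, e) for fid, s, e in self.events if _stem(fid).lower() == key
        ]


def _stem(name: str) -> str:
    return Path(name).stem


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

def _ascii_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num_field(value: float, width: int) -> bytes:
    if value == int(value):
        s = str(int(value))
    else:
        s = f"{value:.{width}g}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as a 16-bit EDF file.

    Physical limits per channel are the symmetric integer bound
    ``±ceil(max(|signal|))`` so the header's 8-character ASCII number fields
    are exact; digital limits are −32768..32767, giving a quantization step
    of ``2·pmax/65535`` microvolts.  Signals whose length is not a whole
    number of 1-second records are zero-padded in the final record.

    Raises
    ------
    ValueError
        If the recording has non-finite samples or no channels.
    """
    if rec.n_channels == 0:
        raise ValueError("cannot write an EDF with no channels")
    if not np.isfinite(rec.signals).all():
        raise ValueError("signals contain non-finite samples")

    n_sig = rec.n_channels
    spr = rec.sample_rate  # one-second records
    n_records = math.ceil(rec.n_samples / spr)

    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(
        1.0, np.ceil(np.max(np.abs(rec.signals), axis=1))
    )
    for ch, pmax in enumerate(phys_max):
        if len(str(int(pmax))) > 8:
            raise ValueError(
                f"channel {rec.channel_labels[ch]!r}: amplitude {pmax} "
                "exceeds the representable EDF physical range"
            )

    start = rec.start_time or _dt.datetime(2000, 1, 1, 0, 0, 0)
    header_bytes = _EDF_HEADER_LEN + n_sig * _EDF_SIGNAL_HEADER_LEN

    parts = [
        _ascii_field("0", 8),
        _ascii_field("X X X X", 80),
        _ascii_field(f"Startdate X X X {rec.file_id or 'X'}", 80),
        _ascii_field(start.strftime("%d.%m.%y"), 8),
        _ascii_field(start.strftime("%H.%M.%S"), 8),
        _num_field(header_bytes, 8),
        _ascii_field("", 44),
        _num_field(n_records, 8),
        _num_field(1, 8),
        _num_field(n_sig, 4),
    ]
    for label in rec.channel_labels:
        parts.append(_ascii_field(label, 16))
    parts.append(_ascii_field("", 80) * n_sig)  # transducer
    parts.append(_ascii_field("uV", 8) * n_sig)
    for pmax in phys_max:
        parts.append(_num_field(-pmax, 8))
    for pmax in phys_max:
        parts.append(_num_field(pmax, 8))
    parts.append(_num_field(dig_min, 8) * n_sig)
    parts.append(_num_field(dig_max, 8) * n_sig)
    parts.append(_ascii_field("", 80) * n_sig)  # prefilter
    parts.append(_num_field(spr, 8) * n_sig)
    parts.append(_ascii_field("", 32) * n_sig)

    total = n_records * spr
    padded = np.zeros((n_sig, total))
    padded[:, : rec.n_samples] = rec.signals
    gain = (2.0 * phys_max) / (dig_max - dig_min)
    digital = np.rint(
        (padded + phys_max[:, None]) / gain[:, None] + dig_min
    ).astype(np.int16)

    # interleave: per record, all samples of signal 0, then signal 1, ...
    records = digital.reshape(n_sig, n_records, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        fh.write(records.astype("<i2").tobytes())


def _read_num(raw: bytes, name: str) -> float:
    text = raw.decode("ascii", errors="replace").strip()
    try:
        return float(text)
    except ValueError:
        raise EdfParseError(
            f"EDF header field {name!r} is not numeric: {text!r}"
        ) from None


_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6, "": 1.0}


def read_edf(path: str | Path) -> Recording:
    """Read a 16-bit EDF file into a :class:`Recording`.

    Physical units are standardized to microvolts when the dimension field
    is recognized (uV/mV/V); unrecognized dimensions are passed through
    unscaled.  Channel labels are preserved verbatim.

    Raises
    ------
    EdfParseError
        On a truncated or malformed header (the message names the offending
        field), or if channels declare differing sampling rates (the
        message lists the rates).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HEADER_LEN)
        if len(head) < _EDF_HEADER_LEN:
            raise EdfParseError(
                f"{path.name}: truncated EDF, fixed header is "
                f"{len(head)} < 256 bytes"
            )
        n_records = int(_read_num(head[236:244], "number of data records"))
        record_dur = _read_num(head[244:252], "duration of a data record")
        n_sig = int(_read_num(head[252:256], "number of signals"))
        if n_sig < 1:
            raise EdfParseError("EDF header field 'number of signals' < 1")
        if record_dur <= 0:
            raise EdfParseError(
                "EDF header field 'duration of a data record' must be > 0"
            )

        sig_head = fh.read(n_sig * _EDF_SIGNAL_HEADER_LEN)
        if len(sig_head) < n_sig * _EDF_SIGNAL_HEADER_LEN:
            raise EdfParseError(
                f"{path.name}: truncated EDF, signal header ends early"
            )

        def col(offset: int, width: int) -> list[bytes]:
            base = offset * n_sig
            return [
                sig_head[base + i * width : base + (i + 1) * width]
                for i in range(n_sig)
            ]

        labels = [b.decode("ascii", "replace").rstrip() for b in col(0, 16)]
        units = [
            b.decode("ascii", "replace").strip() for b in col(96, 8)
        ]
        phys_min = np.array(
            [_read_num(b, "physical minimum") for b in col(104, 8)]
        )
        phys_max = np.array(
            [_read_num(b, "physical maximum") for b in col(112, 8)]
        )
        dig_min = np.array(
            [_read_num(b, "digital minimum") for b in col(120, 8)]
        )
        dig_max = np.array(
            [_read_num(b, "digital maximum") for b in col(128, 8)]
        )
        spr = np.array(
            [
                int(_read_num(b, "samples per record"))
                for b in col(216, 8)
            ]
        )
        if (dig_max <= dig_min).any():
            raise EdfParseError(
                "EDF header field 'digital maximum' must exceed "
                "'digital minimum'"
            )
        if (phys_max <= phys_min).any():
            raise EdfParseError(
                "EDF header field 'physical maximum' must exceed "
                "'physical minimum'"
            )
        rates = sorted({s / record_dur for s in spr})
        if len(rates) > 1:
            raise EdfParseError(
                f"channels declare differing sampling rates: {rates}"
            )
        rate = rates[0]
        if rate != int(rate) or rate <= 0:
            raise EdfParseError(
                f"non-integer sampling rate {rate} not supported"
            )

        data = np.frombuffer(fh.read(), dtype="<i2")

    per_record = int(spr.sum())
    if n_records < 0:  # -1 means "unknown" per the EDF spec
        n_records = len(data) // per_record
    if len(data) < n_records * per_record:
        raise EdfParseError(
            f"{path.name}: data area holds {len(data)} samples, header "
            f"declares {n_records * per_record}"
        )
    data = data[: n_records * per_record]

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    scale = np.array(
        [_UNIT_TO_UV.get(u.lower(), 1.0) for u in units]
    )

    signals = np.empty((n_sig, n_records * int(spr[0])))
    recs = data.reshape(n_records, per_record)
    offs = np.concatenate([[0], np.cumsum(spr)])
    for i in range(n_sig):
        raw = recs[:, offs[i] : offs[i + 1]].reshape(-1).astype(np.float64)
        signals[i] = ((raw - dig_min[i]) * gain[i] + phys_min[i]) * scale[i]

    start_time = None
    try:
        d = head[168:176].decode("ascii").strip()
        t = head[176:184].decode("ascii").strip()
        dd, mm, yy = (int(x) for x in d.split("."))
        hh, mi, ss = (int(x) for x in t.split("."))
        year = yy + (2000 if yy < 85 else 1900)
        start_time = _dt.datetime(year, mm, dd, hh, mi, ss)
    except (ValueError, UnicodeDecodeError):
        pass

    return Recording(
        channel_labels=labels,
        sample_rate=int(rate),
        signals=signals,
        start_time=start_time,
        file_id=path.stem,
    )


# ---------------------------------------------------------------------------
# CHB-MIT-style annotation summaries
# ---------------------------------------------------------------------------

_RE_FILE = re.compile(r"^file\s+name\s*:\s*(\S+)", re.I)
_RE_NSEIZ = re.compile(r"^number\s+of\s+seizures\s+in\s+file\s*:\s*(\d+)", re.I)
_RE_START = re.compile(
    r"^seizure\s*(?:\d+\s+)?start\s+time\s*:\s*([\d.]+)\s*sec", re.I
)
_RE_END = re.compile(
    r"^seizure\s*(?:\d+\s+)?end\s+time\s*:\s*([\d.]+)\s*sec", re.I
)
_RE_FSTART = re.compile(r"^file\s+start\s+time\s*:\s*(\d+):(\d+):(\d+)", re.I)
_RE_FEND = re.compile(r"^file\s+end\s+time\s*:\s*(\d+):(\d+):(\d+)", re.I)


def parse_annotation_summary(path: str | Path) -> AnnotationSet:
    """Parse a CHB-MIT-style plain-text seizure summary.

    Handles both the bare ("Seizure Start Time:") and the numbered
    ("Seizure 1 Start Time:") dialects; all other lines (sampling rate,
    channel lists, ...) are ignored.  File durations are derived from the
    declared start/end clock times where present, allowing a single
    midnight wrap.

    Raises
    ------
    EdfParseError
        If a file block declares N seizures but a different number of
        start/end pairs is found, or an event ends at or before its start.
    """
    path = Path(path)
    events: list[tuple[str, float, float]] = []
    durations: dict[str, float] = {}
    total_files = 0

    current: str | None = None
    declared = 0
    starts: list[float] = []
    ends: list[float] = []
    fstart: float | None = None

    def close_block() -> None:
        nonlocal current, declared, starts, ends, fstart
        if current is None:
            return
        if len(starts) != declared or len(ends) != declared:
            raise EdfParseError(
                f"{current}: declares {declared} seizures but "
                f"{len(starts)} start / {len(ends)} end times parsed"
            )
        for s, e in zip(starts, ends):
            if e <= s:
                raise EdfParseError(
                    f"{current}: seizure end {e} <= start {s}"
                )
            dur = durations.get(_stem(current))
            if dur is not None:
                s, e = min(s, dur), min(e, dur)
                if e <= s:
                    continue
            events.append((_stem(current), float(s), float(e)))
        current, declared, starts, ends, fstart = None, 0, [], [], None

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if m := _RE_FILE.match(line):
            close_block()
            current = m.group(1)
            total_files += 1
            continue
        if current is None:
            continue
        if m := _RE_FSTART.match(line):
            h, mi, s = (int(x) for x in m.groups())
            fstart = h * 3600 + mi * 60 + s
        elif m := _RE_FEND.match(line):
            h, mi, s = (int(x) for x in m.groups())
            fend = h * 3600 + mi * 60 + s
            if fstart is not None:
                dur = fend - fstart
                if dur < 0:
                    dur += 24 * 3600
                durations[_stem(current)] = float(dur)
        elif m := _RE_NSEIZ.match(line):
            declared = int(m.group(1))
        elif m := _RE_START.match(line):
            starts.append(float(m.group(1)))
        elif m := _RE_END.match(line):
            ends.append(float(m.group(1)))
    close_block()

    return AnnotationSet(
        events=events, total_files=total_files, file_durations=durations
    )
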