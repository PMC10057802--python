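"""Overlapping-window FFT featurization of multichannel signals.

Each channel is cut into fixed-length windows of ``window_len`` samples in
which adjacent windows share ``overlap`` samples (hop = window_len −
overlap; defaults 256/64 give a 192-sample hop, a ¾-second step at
256 Hz).  Every window becomes the modulus of its full discrete Fourier
transform — a conjugate-symmetric, ``window_len``-dimensional magnitude
vector.  The full (redundant) spectrum rather than the one-sided half is
kept so the feature dimension equals the window length, matching the 4:1
bottleneck of the downstream autoencoder.  No taper is applied by default;
a Hann taper is selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FrameConfig",
    "SpectralFrames",
    "SpectralFramer",
    "window_signal",
    "fft_magnitude",
    "featurize",
    "frame_count",
]


@dataclass(frozen=True)
class FrameConfig:
    """Windowing geometry.

    ``overlap`` is the number of samples shared by adjacent windows, so the
    hop (window start increment) is ``window_len - overlap``.
    """

    window_len: int = 256
    overlap: int = 64
    taper: str | None = None  # None (rectangular) or "hann"

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0 <= self.overlap < self.window_len:
            raise ValueError("need 0 <= overlap < window_len")
        if self.taper not in (None, "hann"):
            raise ValueError(f"unknown taper {self.taper!r}")

    @property
    def hop(self) -> int:
        return self.window_len - self.overlap


@dataclass
class SpectralFrames:
    """Per-channel frame × window_len magnitude matrices.

    ``frames`` has shape (n_channels, F, window_len); ``frame_times`` holds
    the start sample index of each frame and is shared across channels.
    """

    channel_labels: list[str]
    frames: np.ndarray
    frame_times: np.ndarray
    config: FrameConfig = field(default_factory=FrameConfig)
    sample_rate: int = 256

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]


def frame_count(n_samples: int, cfg: FrameConfig) -> int:
    """Number of complete windows: floor((T − window_len)/hop) + 1, or 0."""
    if n_samples < cfg.window_len:
        return 0
    return (n_samples - cfg.window_len) // cfg.hop + 1


def window_signal(signal: np.ndarray, cfg: FrameConfig) -> np.ndarray:
    """Cut one channel into overlapping windows.

    Window ``i`` covers samples ``[i*hop, i*hop + window_len)``; trailing
    samples that do not fill a complete window are dropped.  Returns an
    (F, window_len) array; F = 0 (with a warning) when the signal is
    shorter than one window.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    n = frame_count(signal.shape[0], cfg)
    if n == 0:
        warnings.warn(
            f"signal of {signal.shape[0]} samples is shorter than one "
            f"window ({cfg.window_len}); no frames produced",
            stacklevel=2,
        )
        return np.empty((0, cfg.window_len))
    return sliding_window_view(signal, cfg.window_len)[:: cfg.hop][:n].copy()


def fft_magnitude(window: np.ndarray, taper: str | None = None) -> np.ndarray:
    """Full DFT magnitude of one window (length preserved, mean kept).

    Element k is ``|Σ_n x[n]·exp(−2πi·k·n/L)|``; the spectrum is conjugate-
    symmetric, so bins k and L−k coincide.  A constant window c maps to
    L·|c| in bin 0 and zeros elsewhere.
    """
    window = np.asarray(window, dtype=np.float64)
    if not np.isfinite(window).all():
        raise ValueError("window contains non-finite samples")
    if taper == "hann":
        window = window * np.hanning(window.shape[-1])
    return np.abs(np.fft.fft(window, axis=-1))


def featurize(rec, cfg: FrameConfig | None = None) -> SpectralFrames:
    """Window + FFT-magnitude every channel of a recording independently.

    Accepts a :class:`~eeganomaly.io.Recording` or a (n_channels, T)
    array.  Channels are processed independently; deleting or permuting
    channels permutes the output identically.
    """
    cfg = cfg or FrameConfig()
    if hasattr(rec, "signals"):
        signals = rec.signals
        labels = list(rec.channel_labels)
        rate = rec.sample_rate
    else:
        signals = np.atleast_2d(np.asarray(rec, dtype=np.float64))
        labels = [f"ch{i}" for i in range(signals.shape[0])]
        rate = 256
    n = frame_count(signals.shape[1], cfg)
    frame_times = np.arange(n) * cfg.hop
    mats = np.empty((signals.shape[0], n, cfg.window_len))
    for i in range(signals.shape[0]):
        mats[i] = fft_magnitude(window_signal(signals[i], cfg), cfg.taper)
    return SpectralFrames(
        channel_labels=labels,
        frames=mats,
        frame_times=frame_times,
        config=cfg,
        sample_rate=rate,
    )


class SpectralFramer(TransformerMixin, BaseEstimator):
    """Transformer from raw channels to FFT-magnitude frames.

    ``transform`` maps an (n_channels, T) array to an
    (n_channels, F, window_len) stack of magnitude spectra.  Stateless;
    ``fit`` only validates parameters.

    Parameters
    ----------
    window_len : int, default 256
        Samples per analysis window (1 s at 256 Hz).
    overlap : int, default 64
        Samples shared by adjacent windows; hop = window_len − overlap.
    taper : {None, "hann"}, default None
        Amplitude taper applied before the FFT.
    """

    def __init__(
        self,
        window_len: int = 256,
        overlap: int = 64,
        taper: str | None = None,
    ):
        self.window_len = window_len
        self.overlap = overlap
        self.taper = taper

    def _config(self) -> FrameConfig:
        return FrameConfig(self.window_len, self.overlap, self.taper)

    def fit(self, X, y=None):
        self._config()  # parameter validation
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return featurize(X, self._config()).frames

    def frame_times(self, n_samples: int) -> np.ndarray:
        cfg = self._config()
        return np.arange(frame_count(n_samples, cfg)) * cfg.hop
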