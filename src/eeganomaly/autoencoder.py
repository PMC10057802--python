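"""Per-recording bottleneck autoencoder and reconstruction-error scoring.

A single-hidden-layer autoencoder (256 → 64 → 256, leaky-ReLU hidden,
linear output) is trained on one channel's FFT-magnitude frames with mean-
squared-error loss.  Because the bottleneck is a quarter of the input
dimension, the network can only compress the frequency patterns that
dominate the recording's background; frames whose spectra fall outside
that learned subspace reconstruct poorly, and the element-wise absolute
reconstruction error is the anomaly signal handed to the segmenter.

Training is squared-error; the *reported* error is the absolute
difference, on the original magnitude scale even when inputs are
normalized for training.
"""

from __future__ import annotations

import numpy as np
import h5py
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FrameAutoencoder",
    "init_model",
    "train",
    "reconstruction_error",
]


class FrameAutoencoder(TransformerMixin, BaseEstimator):
    """256→64→256 autoencoder scoring frames by reconstruction error.

    Parameters
    ----------
    hidden_dim : int, default 64
        Bottleneck width; must be smaller than the input dimension.
    negative_slope : float, default 0.01
        Leaky-ReLU slope for negative pre-activations (hidden layer only;
        the decoder output is linear).
    learning_rate : float, default 0.001
    epochs : int, default 25
        Full passes over the frames.
    batch_size : int or None, default 16
        Frames per gradient step; ``None`` trains full-batch, in which
        case the fit is invariant to frame order.
    optimizer : {"adam", "sgd"}, default "adam"
        "sgd" is plain gradient descent at ``learning_rate``.
    normalize_input : bool, default True
        Scale frames by the channel's maximum frame magnitude before
        training.  The scale is stored so errors are reported on the
        original scale.  Raw FFT magnitudes of microvolt signals span
        ~1e4, far outside the regime where a fixed 1e-3 learning rate is
        useful, so this is on by default; disabling it reproduces the
        literal unnormalized recipe.
    random_state : int, default 0
        Seed for weight initialization and minibatch shuffling.

    Attributes
    ----------
    W_enc_, b_enc_, W_dec_, b_dec_ : ndarray
        Fitted weights, shapes (hidden, input), (hidden,), (input, hidden),
        (input,).
    loss_trace_ : ndarray, shape (epochs,)
        Mean training MSE per epoch (pre-update for full batch).
    scale_ : float
        Normalization divisor recorded at fit (1.0 when disabled).
    """

    def __init__(
        self,
        hidden_dim: int = 64,
        negative_slope: float = 0.01,
        learning_rate: float = 0.001,
        epochs: int = 25,
        batch_size: int | None = 16,
        optimizer: str = "adam",
        normalize_input: bool = True,
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.negative_slope = negative_slope
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.normalize_input = normalize_input
        self.random_state = random_state

    # -- initialization ----------------------------------------------------

    def _validate(self, input_dim: int) -> None:
        if self.hidden_dim >= input_dim:
            raise ValueError(
                f"hidden_dim ({self.hidden_dim}) must be < input "
                f"dimension ({input_dim})"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def initialize(self, input_dim: int = 256) -> "FrameAutoencoder":
        """Draw Glorot-uniform weights (±sqrt(6/(fan_in+fan_out))), zero
        biases, reproducibly under ``random_state``."""
        self._validate(input_dim)
        rng = np.random.default_rng(self.random_state)
        limit = np.sqrt(6.0 / (input_dim + self.hidden_dim))
        self.W_enc_ = rng.uniform(
            -limit, limit, size=(self.hidden_dim, input_dim)
        )
        self.b_enc_ = np.zeros(self.hidden_dim)
        self.W_dec_ = rng.uniform(
            -limit, limit, size=(input_dim, self.hidden_dim)
        )
        self.b_dec_ = np.zeros(input_dim)
        self.n_features_in_ = input_dim
        self.scale_ = 1.0
        self.loss_trace_ = np.zeros(0)
        return self

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray):
        pre = X @ self.W_enc_.T + self.b_enc_
        hid = np.where(pre >= 0, pre, self.negative_slope * pre)
        out = hid @ self.W_dec_.T + self.b_dec_
        return pre, hid, out

    def _step(self, X: np.ndarray, opt_state: dict) -> float:
        n, d = X.shape
        pre, hid, out = self._forward(X)
        resid = out - X
        with np.errstate(over="ignore", invalid="ignore"):
            loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training loss diverged to a non-finite value; enable "
                "normalize_input or lower the learning rate"
            )
        # d loss / d out, MSE averaged over batch and dims
        g_out = (2.0 / (n * d)) * resid
        g_Wdec = g_out.T @ hid
        g_bdec = g_out.sum(axis=0)
        g_hid = g_out @ self.W_dec_
        g_pre = g_hid * np.where(pre >= 0, 1.0, self.negative_slope)
        g_Wenc = g_pre.T @ X
        g_benc = g_pre.sum(axis=0)

        grads = {
            "W_enc_": g_Wenc,
            "b_enc_": g_benc,
            "W_dec_": g_Wdec,
            "b_dec_": g_bdec,
        }
        if self.optimizer == "sgd":
            for k, g in grads.items():
                setattr(self, k, getattr(self, k) - self.learning_rate * g)
        else:  # adam
            opt_state["t"] += 1
            t = opt_state["t"]
            b1, b2, eps = 0.9, 0.999, 1e-8
            for k, g in grads.items():
                m = opt_state["m"][k] = b1 * opt_state["m"][k] + (1 - b1) * g
                v = opt_state["v"][k] = b2 * opt_state["v"][k] + (
                    1 - b2
                ) * g**2
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                setattr(
                    self,
                    k,
                    getattr(self, k)
                    - self.learning_rate * mhat / (np.sqrt(vhat) + eps),
                )
        return loss

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None) -> "FrameAutoencoder":
        """Train on an (F, input_dim) frame matrix for exactly ``epochs``
        passes, recording the per-epoch mean loss."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty (F, input_dim) matrix")
        self.initialize(X.shape[1])
        if self.normalize_input:
            peak = float(np.max(np.abs(X)))
            self.scale_ = peak if peak > 0 else 1.0
        Xn = X / self.scale_

        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 1])
        )
        opt_state = {
            "t": 0,
            "m": {k: 0.0 for k in ("W_enc_", "b_enc_", "W_dec_", "b_dec_")},
            "v": {k: 0.0 for k in ("W_enc_", "b_enc_", "W_dec_", "b_dec_")},
        }
        n = Xn.shape[0]
        bs = n if self.batch_size is None else min(self.batch_size, n)
        trace = np.empty(self.epochs)
        for epoch in range(self.epochs):
            if bs == n:
                trace[epoch] = self._step(Xn, opt_state)
            else:
                order = rng.permutation(n)
                losses, weights = [], []
                for lo in range(0, n, bs):
                    idx = order[lo : lo + bs]
                    losses.append(self._step(Xn[idx], opt_state))
                    weights.append(len(idx))
                trace[epoch] = float(np.average(losses, weights=weights))
        self.loss_trace_ = trace
        return self

    def reconstruct(self, X) -> np.ndarray:
        """Decode(encode(X)) on the original scale."""
        check_is_fitted(self, "W_enc_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[-1]}"
            )
        _, _, out = self._forward(X / self.scale_)
        return out * self.scale_

    def transform(self, X) -> np.ndarray:
        """Element-wise absolute reconstruction error, original scale."""
        X = np.asarray(X, dtype=np.float64)
        return np.abs(X - self.reconstruct(X))

    def score_frames(self, X) -> np.ndarray:
        """Scalar per-frame error: mean of the error vector components."""
        return self.transform(X).mean(axis=-1)

    # -- persistence -------------------------------------------------------

    _H5_KEYS = ("W_enc_", "b_enc_", "W_dec_", "b_dec_", "loss_trace_")

    def save(self, group: "h5py.Group | str") -> None:
        """Persist weights + config to an HDF5 group or new file."""
        check_is_fitted(self, "W_enc_")
        own = isinstance(group, str)
        h = h5py.File(group, "w") if own else group
        try:
            for k in self._H5_KEYS:
                h.create_dataset(k, data=getattr(self, k))
            h.attrs["scale_"] = self.scale_
            h.attrs["n_features_in_"] = self.n_features_in_
            for k, v in self.get_params().items():
                h.attrs[f"param_{k}"] = "none" if v is None else v
        finally:
            if own:
                h.close()

    @classmethod
    def load(cls, group: "h5py.Group | str") -> "FrameAutoencoder":
        own = isinstance(group, str)
        h = h5py.File(group, "r") if own else group
        try:
            params = {
                k[len("param_") :]: (None if v == "none" else v)
                for k, v in h.attrs.items()
                if k.startswith("param_")
            }
            for key in ("hidden_dim", "epochs", "random_state"):
                if params.get(key) is not None:
                    params[key] = int(params[key])
            if params.get("batch_size") is not None:
                params["batch_size"] = int(params["batch_size"])
            params["normalize_input"] = bool(params["normalize_input"])
            model = cls(**params)
            for k in cls._H5_KEYS:
                setattr(model, k, np.asarray(h[k]))
            model.scale_ = float(h.attrs["scale_"])
            model.n_features_in_ = int(h.attrs["n_features_in_"])
            return model
        finally:
            if own:
                h.close()


# -- functional wrappers ----------------------------------------------------

def init_model(config: dict | None = None, input_dim: int = 256) -> FrameAutoencoder:
    """Build and initialize an untrained model from a parameter dict."""
    return FrameAutoencoder(**(config or {})).initialize(input_dim)


def train(model: FrameAutoencoder, frames: np.ndarray) -> FrameAutoencoder:
    """Fit ``model`` on one channel's (F, input_dim) frame matrix."""
    return model.fit(frames)


def reconstruction_error(
    model: FrameAutoencoder, frames: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(error_vectors, scalar_errors): |input − reconstruction| per frame
    and its mean over components."""
    vec = model.transform(frames)
    return vec, vec.mean(axis=-1)
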