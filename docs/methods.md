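# Methods

## Model and assumptions

The pipeline rests on one assumption: within a single channel of a single
recording, normal background activity dominates in time and is spectrally
compressible, while the events of interest are rare and spectrally
different. Everything else follows from that. The autoencoder is a
background model — trained on *all* frames of the channel, anomalies
included, it still converges toward the dominant patterns because the
rare frames contribute little to the loss. Its reconstruction error is
therefore a per-frame novelty score with frequency localization (a
256-vector, one entry per DFT bin). The segmenter turns that score into
piecewise-constant state labels so that flagged time is contiguous and
reviewable, rather than a per-frame threshold crossing.

No information crosses channels or recordings. This buys montage
independence and embarrassing parallelism at the price of ignoring the
spatial correlation of real discharges (which the channel-coincidence
statistic then recovers descriptively).

## Framing and spectral features

- `window_len = 256` samples, `overlap = 64` → hop 192 (¾ s at 256 Hz).
  "Overlap" means samples *shared* by adjacent windows. The alternative
  reading (hop = 64) is available by setting `overlap = 192`.
- Features are the **full** 256-point DFT magnitude, conjugate-symmetric
  and hence 2× redundant. The redundancy is deliberate: it keeps the
  feature dimension equal to the window length so the autoencoder's
  64-unit hidden layer is exactly a quarter of its input.
- No taper is applied by default (rectangular window); `taper="hann"` is
  available. Magnitudes are used raw — no log, no per-bin standardization.
- Frame count follows the closed form F = ⌊(T − 256)/192⌋ + 1; trailing
  samples are dropped; a signal shorter than one window yields zero
  frames and a warning rather than an error.

## Autoencoder

Architecture: one linear encoder (256→64), leaky-ReLU (α = 0.01), one
linear decoder (64→256). Training loss is MSE averaged over batch and
components; the *reported* error is the element-wise absolute difference,
the conventional split between a differentiable objective and an
interpretable residual.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `hidden_dim` | 64 | bottleneck width (¼ of input) |
| `learning_rate` | 0.001 | Adam step size |
| `epochs` | 25 | full passes over the channel's frames |
| `batch_size` | 16 | frames per gradient step (`None` = full batch) |
| `optimizer` | `adam` | or `sgd` (plain gradient descent) |
| `normalize_input` | `True` | divide frames by the channel's max magnitude |
| `random_state` | — | seeds Glorot-uniform init and batch shuffling |

Two of these deserve justification. **Optimizer/batch size:** with 25
epochs fixed, plain full-batch gradient descent at lr 0.001 performs ~25
tiny parameter updates and leaves the network essentially at its random
initialization; the anomaly-contrast property that the whole method
depends on (background frames reconstructing much better than
off-subspace frames) then fails outright. Adam with minibatches of 16
reaches ≥ 8× contrast on rank-64 background fixtures within the same 25
epochs, so that is the default; both knobs remain exposed.
**Normalization:** raw FFT magnitudes of microvolt EEG reach ~10⁴, far
outside the regime where a fixed 10⁻³ learning rate trains anything.
Frames are scaled by the channel's maximum absolute magnitude before
training; the divisor is stored on the model and errors are rescaled, so
downstream stages always see errors in the original units.

Training is bit-reproducible given (frames, seed, config). Divergence
(non-finite loss) raises immediately with advice to normalize rather than
propagating NaNs.

## Segmenter

Emission cost: mean squared deviation between the frame's error vector
and a state centroid. Transition penalty 200 and minimum state frequency
20 are the method's two fixed constants; the penalty is additive per
state *change* in the path, which makes 200 commensurate with
mean-squared costs of error vectors in original (microvolt-scale) units.
The Viterbi recursion is exact, O(F·K); ties are broken toward the lower
state id so results are identical across platforms.

The generative loop: start with one state at the global centroid, then
repeat — segment, re-estimate centroids from claimed frames, prune states
claiming < 20 frames (their frames are reabsorbed on the next pass),
propose a new state from the contiguous window of 20 frames with the
highest mean emission cost, keep the proposal only if total path cost
drops. The proposal window is `min_frequency` frames long because that is
the shortest stretch that could sustain a surviving state; note that
proposing from same-state *runs* of the current segmentation would be
unable to propose anything from the initial single-run segmentation.
The loop is capped at 20 proposals and is fully deterministic. A sequence
shorter than `min_frequency` keeps its single global state (the pruning
invariant is vacuous there by design).

Anomaly binarization: the modal state is background; by default every
other state is flagged (`flag_policy="nonmodal"`). The alternative
(`"error_ratio"`): flag only states whose mean scalar error exceeds the
background's by a factor (default 2.0) — useful when background activity
itself splits into several benign states.

The segmenter input is the full 256-dim error vector by default
(`hmm_input="error_vec"`); scalar error and raw spectrum variants exist
for sensitivity analysis.

## Evaluation

Frame truth uses the most permissive rule — ≥ 1 sample of overlap between
the frame's window and an annotated event — because events only partially
overlap fixed frames and per-frame sensitivity is already a lower bound.
A frame is globally flagged when ≥ `min_channels` channels flag it
(default 1). Multi-recording aggregation sums confusion counts
(micro-averaging); macro means are easily computed from the per-file
reports. Metrics with zero denominators are reported as `null`, never
coerced to 0. Event capture: an event counts as detected if any channel
flags any frame overlapping it; channel coincidence is the fraction of
channels that do.

## Synthetic data generator

The generator emulates the statistics the detector is sensitive to:

- background: per channel, one alpha (8–12 Hz) and one theta (4–7 Hz)
  sinusoid with random frequency and phase (30/20 µV) plus white Gaussian
  noise (10 µV) — ~27 µV RMS, ordinary awake scalp EEG scale;
- events: ~3 Hz spike-and-wave bursts (sharp transient + slow wave each
  cycle, hence a 3 Hz fundamental with harmonics) scaled to 4× the
  background RMS, planted at whole-second, non-overlapping intervals with
  10 s margins; default 3 events of 10–60 s in a 10-minute recording,
  capped at 20% of total time.

Defaults are scaled down from hours-long clinical recordings where
seizures occupy ~0.3% of time and last 6–750 s; event rarity is relaxed
so that desk-scale fixtures exercise the detector in minutes. What the
generator does *not* emulate — inter-channel correlation, artifacts
(blinks, EMG, electrode pops), non-stationary background — bounds what
passing tests show: they demonstrate the mechanism (background
compression + error segmentation) under controlled contrast, not clinical
performance.

## Numerical and design choices

- EDF: plain 16-bit EDF, 1-second records; physical limits are symmetric
  integers ⌈max|x|⌉ so the 8-character ASCII header fields are exact and
  the write→read round trip deviates by at most one quantization step
  (2·pmax/65535). Signals not a whole number of seconds are zero-padded
  in the final record. Reading standardizes recognized units (uV/mV/V) to
  microvolts; unrecognized unit strings pass through unscaled. Channels
  with non-signal labels ("-", "VNS", duplicates) are processed like any
  other; CLI glob filters (`--include-channels/--exclude-channels`)
  exclude by label pattern.
- Annotation summaries: both the bare and numbered seizure-time dialects
  are parsed; declared-count mismatches are errors naming the file; file
  durations come from declared clock times (one midnight wrap allowed)
  and events are clipped to them. Annotations attach to recordings by
  case-insensitive file-stem match.
- Determinism: per-channel seeds are derived from the run seed and the
  channel index, so results are byte-identical across repeated runs,
  channel orderings, and worker counts; the run manifest (all parameters
  + seed + version) suffices to reproduce a run exactly.
- Emission costs in the Viterbi are computed via the expanded quadratic
  (‖x‖² − 2x·c + ‖c‖²)/D, clipped at 0 against cancellation.

## Problem sizes used in the shipped checks

Oracle and study sizes were chosen to be decisive yet desk-scale: 500
random instances for the exact-Viterbi cross-check (T ≤ 8, K ≤ 3, against
exhaustive enumeration), 100 planted-segmentation simulations, 10 seeds
for the anomaly-contrast bound, 1000 random confusion tables for the
metric formulas, and an end-to-end study of 20 fixtures (8 channels ×
10 min × 3 events). All run in a few minutes on one CPU.

## Known limitations

- Per-frame flags inherit the frame geometry: onset/offset resolution is
  one hop (0.75 s), and events shorter than a window are smeared.
- A channel whose autoencoder happens to reconstruct events well (e.g.
  when events dominate a short recording) yields a single state and no
  flags; in multichannel recordings other channels compensate, which is
  what the coincidence statistic measures.
- The transition penalty and minimum frequency are fixed constants, not
  adapted to recording length; very short recordings (< 20 frames) cannot
  produce any flags under the default policy.
- The 5× anomaly-contrast property is demonstrated on linear-subspace
  fixtures; real EEG backgrounds are not linear subspaces, and contrast
  on clinical data will be lower.
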