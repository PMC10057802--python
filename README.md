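# eeganomaly

Unsupervised, per-channel anomaly labeling for multichannel EEG recordings.

Long clinical EEG recordings are reviewed manually by specialists, yet the
events of interest — epileptiform discharges — occupy well under 1% of the
recorded time. `eeganomaly` automates the triage step: it learns each
recording's own background activity and labels the stretches that deviate
from it, so an expert only needs to review the flagged segments. No
training data, annotations, or cross-patient models are involved; every
recording (indeed, every channel) is analyzed from scratch.

## Method

For each channel independently:

1. **Framing + FFT.** The signal is cut into overlapping windows of 256
   samples (1 s at 256 Hz) with a hop of 192 samples, and each window is
   mapped to its full 256-point DFT magnitude vector |X_k|.
2. **Autoencoder error.** A single-hidden-layer autoencoder
   (256 → 64 → 256, leaky-ReLU hidden layer, linear decoder) is trained on
   that channel's frames with MSE loss (learning rate 0.001, 25 epochs).
   The 4:1 bottleneck can only compress the dominant background spectra;
   the per-frame error vector e_t = |x_t − x̂_t| is the anomaly signal.
3. **Penalized-Viterbi segmentation.** Frames are assigned to discrete
   states by minimizing Σ_t d(e_t, c_{s_t}) + λ·#transitions, where
   d is the mean squared deviation from a state centroid and λ = 200 is
   the transition penalty. States are hypothesized generatively: starting
   from one global state, the worst-explained contiguous stretch proposes
   a new state, and states claiming fewer than 20 frames are pruned.
4. **Labeling.** The modal state is "background"; frames in any other
   state are candidate anomalies. Event-level capture and channel
   coincidence are computed against annotations when available.

The per-channel design makes runs embarrassingly parallel, O(T) per
channel, and montage-agnostic.

## Worked example

```python
from eeganomaly import SynthConfig, generate, RunConfig, run_recording
from eeganomaly.pipeline import evaluate_run

# 8-channel, 10-minute synthetic EEG with 3 planted spike-wave discharges
rec, ann = generate(SynthConfig(seed=3))
result = run_recording(rec, RunConfig(seed=3))
report = evaluate_run(result, ann)

print(f"channels: {len(result.channels)}, frames per channel: {len(result.frame_times)}")
print(f"states per channel: {[c.states.n_states for c in result.channels]}")
print(f"captured: {report['event_capture']['captured']}/{report['event_capture']['total']}")
print(f"frame sensitivity: {report['sensitivity']:.3f}  specificity: {report['specificity']:.3f}")
```

prints

```
channels: 8, frames per channel: 799
states per channel: [3, 2, 3, 2, 2, 2, 2, 2]
captured: 3/3
frame sensitivity: 1.000  specificity: 1.000
```

Each channel settled on 2–3 states: one background state absorbing the
alpha/theta mixture, plus anomaly state(s) claiming the discharge frames.
All three planted events were captured with every frame correctly
classified on this fixture.

The same pipeline runs from the shell on EDF files:

```bash
eeganomaly synth -o fixtures --seed 9            # make a test recording
eeganomaly run fixtures/synth009.edf -o out \
    --annotations fixtures/synth009-summary.txt  # analyze + evaluate
eeganomaly batch edf_dir/ -o out --workers 4     # whole directories
```

Outputs per recording: a state-track TSV (channel, frame, state, error,
flag), per-channel model weights (HDF5), a manifest that reproduces the
run bit-identically, and a metrics JSON when annotations are given.

## Scope

Input is plain 16-bit EDF plus optional CHB-MIT-style plain-text seizure
summaries. The tool flags *candidate* anomalies to concentrate expert
attention; it does not produce diagnoses. See `docs/methods.md` for model
assumptions, parameter semantics, and known limitations.
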