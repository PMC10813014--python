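# Methods

This note documents the models and procedures implemented in
`emgtune`, the choices made where the design was genuinely open, and
what the synthetic data can and cannot show.

## Synthetic sEMG model

Each trial is `rest_s` (default 2 s) of broadband noise floor followed
by `movement_s` (default 4 s) of movement activity on `n_channels`
(default 4) channels at `fs` = 1500 Hz. The movement-span signal on
channel *c* for movement *m* is

```
x_c(t) = floor_c(t) + W[m, c] · g_{s,c} · env(t) · carrier_c(t)
```

* `carrier_c` — Gaussian white noise bandpassed to `carrier_band`
  (default 20–450 Hz, where most surface-EMG energy lives), normalized
  to unit RMS per channel. Surface EMG at the skin is well approximated
  by amplitude-modulated colored noise; no motor-unit action-potential
  model is attempted.
* `env` — a plateau with raised-cosine on/off ramps of `ramp_s`
  (default 0.2 s): a brisk but smooth contraction onset.
* `W` — the 5 × 4 class-channel gain matrix. The default is
  prime-mover dominant: each movement drives its own muscle at gain 1.0
  with 0.1 co-activation elsewhere, and the rest class is all zeros.
  This is deliberately an *easy* configuration: the package's
  end-to-end checks require a fixture on which near-ceiling
  classification is attainable, so that failures indicate pipeline
  defects rather than task difficulty.
* `g_{s,c}` — a per-subject, per-channel log-normal gain
  (`subject_gain_sd`, default 0.1), drawn once per subject. This is the
  single knob creating a cross-subject generalization gap for the
  leave-subject-out splits.
* `floor_c` — white noise with `noise_floor_sd` = 0.03, i.e. roughly
  30 dB below a fully active channel.

Randomness: every trial draws from a named substream keyed by
(seed, subject, movement, trial), and subject gains from
(seed, subject); any subset of the dataset is therefore bit-reproducible
independently of generation order.

**What this generator does not emulate:** powerline interference (the
emulated acquisition chain removes it in analog hardware), electrode
placement and lift-off artifacts, muscle fatigue, and — importantly —
any class-dependent *temporal or spectral* structure. Class identity is
carried entirely by per-channel amplitude. Consequences are discussed
under "Known limitations".

## Preprocessing

Filtering uses a second-order Butterworth bandpass (10–500 Hz)
designed as second-order sections and applied forward-backward
(`sosfiltfilt`), so the effective magnitude response is the square of
the prototype's and the net group delay is zero. "Second order" names
the designed prototype, matching the common Butter + filtfilt idiom.
Filtering happens *before* rest trimming so edge transients fall in the
discarded rest span.

Windowing: 250 ms windows overlapping by 190 ms, i.e. a step of 60 ms
(90 samples at 1.5 kHz). Windows are 0-based with half-open sample
intervals `[start, start + W)`; a trailing partial window is dropped,
giving `floor((L − W)/step) + 1` windows. A 6000-sample retained
movement span yields exactly 63 windows of 375 samples.

Splits are subject-wise: the held-out subjects' windows form the test
set; the remaining windows are shuffled once with a stated seed and
divided 80/20 into training and validation. Presets cover the two study
layouts (train on subjects 1–8, test on 9; train on 1–5, test on 6–9).

## Grey Wolf Optimizer

A population of N candidate vectors in a box. Per iteration
t = 1..T the control scalar is a = 2 − t·(2/T) (so the final iteration
is pure exploitation, a = 0). For each wolf, leader and dimension,
fresh uniforms give A = 2a·r₁ − a and C = 2·r₂; the attraction point
for leader L is X_L − A·|C∘X_L − X_i|, and the new position is the mean
of the three leaders' attraction points, hard-clipped to the box.

Open choices resolved here:

* **Combination rule** — the canonical mean of the three attraction
  points.
* **Leader retention** — α/β/δ are best-so-far over all evaluated
  candidates (elitist), so the best-cost trace is monotone
  non-increasing. Ties break by evaluation order.
* **Coefficient redraw** — per wolf, per leader *and per dimension*.
* **Integer dimensions** — kept continuous inside the optimizer and
  rounded half-up only when a position is decoded for evaluation.
* **Non-finite costs** — treated as +∞ with a logged warning.

Convergence depth at the study budget (20 wolves, 10 iterations) on a
5-dimensional sphere over [−5, 5]⁵ is typically a best cost of a few
times 10⁻², seed-dependent; reaching 10⁻² reliably requires more
iterations. The hyperparameter-recovery diagnostic (a closed-form
quadratic fitness over the actual search box) lands within a few
percent of each coordinate's range at that same budget.

## Recurrent classifiers

A self-contained numpy engine (hand-derived backpropagation, verified
against central finite differences in the test suite) implements:

* stacked **LSTM** (standard 4-gate cells, single bias per gate, unit
  forget-gate bias at init),
* stacked **GRU** in the double-bias ("reset-after") convention —
  separate input and recurrent biases per gate, the reset gate applied
  after the recurrent matrix product,
* stacked **bidirectional LSTM** (forward and backward passes with
  concatenated outputs).

The first recurrent layer returns the full sequence, the second only
its final state, feeding a dense softmax head. SELU replaces tanh as
the cell/candidate activation; gate activations stay sigmoid. An
optional trainable LayerNormalization over the feature axis precedes
the recurrent stack; it is on by default for LSTM/GRU and off for the
bidirectional model — the configuration that reproduces all three
reference parameter counts (76,861 / 33,425 / 48,183). Windows enter
as 4 timesteps × 375 features (channels as the sequence axis), the
unique layout consistent with those counts; the transposed layout is
available via `windows_to_sequences(..., "samples_as_steps")`.

Closed-form parameter counts: layer norm 2f; LSTM 4(u(f+u)+u); GRU
(double-bias) 3(fu+u²+2u); bidirectional doubles its wrapped layer and
the downstream feature width; dense (f_in+1)·K.

Training: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) on categorical
cross-entropy, seeded shuffling and initialization (Glorot-uniform
input weights, orthogonal recurrent blocks), early stopping once
validation accuracy fails to improve for `patience` (default 5)
consecutive epochs, with the best-validation weights restored at the
end. A non-finite loss aborts with a diagnostic; the tuning layer maps
such failures to infinite cost.

## Hyperparameter search

A wolf position is (lr, n1, n2, batch_size, epochs) with default
bounds lr ∈ [1e-5, 0.1], units ∈ [10, 150], batch ∈ [128, 512],
epochs ∈ [10, 100]. Fitness is 1 − best validation accuracy of a model
trained from scratch with the decoded hyperparameters. Each
evaluation's training seed derives from (master seed, wolf, iteration),
so searches are reproducible and evaluations independent. The number
of epochs actually run before early stopping is written back into the
evaluated wolf's epochs dimension (default; advisory logging-only mode
available), so the population drifts toward realized training lengths.
Identical candidates are re-evaluated by default, matching stochastic
training; a cache flag exists for test speed.

## Features and SVM baseline

Six classical time-domain features with explicit thresholds:
waveform length Σ|Δx|; log detector exp(mean log max(|x|, ε));
Shannon entropy of a 32-bin normalized |x| histogram; myopulse
percentage rate with threshold 1.6% of each channel's training-set
maximum amplitude; MMAV1 with weight 1 on the central 50% of samples
and 0.5 outside; zero crossings with a deadband of 1% of each
channel's training-set RMS. The threshold constants are declared
package defaults, recomputed from the training windows by
`calibrate_recipe`. The eight (sensor, feature) assignments follow the
reference configuration and produce an 8-vector per window. The
classifier is a standardized one-vs-one RBF SVM; C and γ are chosen by
validation-set grid search.

## Evaluation

Overall accuracy is correct/total. Per movement class, TP/TN/FP/FN are
tallied one-vs-rest and give accuracy, sensitivity TP/(TP+FN) and
specificity TN/(TN+FP). Zero-denominator metrics are reported as
missing rather than coerced to zero. Reports render percentages with
one decimal and round-trip through the parser at that precision.

## Problem sizes used in the checks

The test suite exercises the full 9 × 20 × 5 windowing arithmetic
(56,700 windows) once, and runs the end-to-end search on a scaled
study: 4 subjects (3 train, 1 held out), 5 trials per movement
(6,300 windows), 4 wolves, 3 iterations, units 8–32, epochs 3–10.
These sizes keep a complete search under a minute per architecture on
one CPU core while preserving every moving part of the method.

## Known limitations

* Because the generator encodes class identity purely in per-channel
  amplitude, the hand-crafted amplitude features are a *lossless*
  summary of the class signal here: the grid-searched RBF SVM
  saturates at 100% held-out accuracy on the default fixture, while
  10-epoch raw-sequence recurrent models converge to ~99.5%. On real
  recordings — where class information also lives in temporal and
  spectral structure that fixed features discard — the ordering
  reverses; passing tests on this generator therefore demonstrate
  pipeline correctness, not the raw-signal advantage itself.
* For the same reason, per-window LayerNormalization (which removes
  each channel's scale) erases most class information on synthetic
  data; the end-to-end checks run all architectures without the input
  normalization layer. On real data the layer is benign and is the
  default for LSTM/GRU.
* The numpy engine is CPU-only and single-threaded by design;
  determinism is bit-exact for a fixed seed on a given BLAS.
* GWO is used at the study budget (hundreds of evaluations); it is not
  a general-purpose global optimizer at that scale, and its
  convergence depth on continuous benchmarks is seed-dependent (see
  above).
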