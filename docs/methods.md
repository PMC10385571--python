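# Methods

## Problem

Human activity *recognition* labels an activity from measured sensor data;
human activity *prediction* (HAP) labels it from data that has not been
measured yet.  `actipred` implements a two-stage HAP pipeline for six-channel
accelerometry (chest + ankle tri-axial ±16 g, 100 Hz): a sequence-to-sequence
forecaster maps the observed first half of a 5.12 s epoch (256 samples) to
the unobserved second half, and a bidirectional-LSTM classifier labels the
forecasted half as one of five locomotion activities (walk, run, Nordic
walk, stairs ascend, stairs descend).

## Preprocessing

Raw PAMAP2-format recordings pass through a fixed stage order:

1. **Edge trim** — the first and last 35 s of each recording are dropped
   (strap-on/strap-off transients).  Configurable; synthetic corpora use 2 s
   since they have no such transients.
2. **Artifact replacement** — NaN samples and samples with per-channel
   |z| > 4 are replaced by the channel mean over unflagged samples.  The 4σ
   threshold is conservative for accelerometry, where genuine impacts reach
   3σ routinely; it is configurable.
3. **Low-pass** — 4th-order Butterworth at 15 Hz, applied forward-backward
   (`filtfilt`).  Zero-phase filtering matters here: a causal filter's group
   delay would shift the observed half relative to the future half and bias
   every forecast target.  Voluntary human movement has negligible energy
   above 15 Hz.
4. **Normalization** — per-channel mean removal, then division by the single
   maximum absolute value across all channels of the recording.  Sharing one
   divisor preserves relative channel amplitudes (an ankle sensor swings
   harder than a chest sensor, and that ratio is informative); per-channel
   scaling is available as an option.  Statistics are per recording.
5. **Smoothing** — centered 5-point moving average with shrinking windows at
   the edges.
6. **Segmentation** — 512-sample windows at stride 256 (50 % overlap) within
   single-activity runs; trailing remainders are discarded.  Overlap
   augments and balances the classes; the stride is configurable
   per corpus.

## Forecasters

All three models map (256, 6) → (256, 6).

**conv2lstm** — two 1-D convolutions (32 filters, kernel 6, ReLU, 'same'
padding) → two LSTM layers → dropout 0.5 → time-distributed projection
(ReLU) → linear channel head.  A direct map with no decoding loop: output
step t is produced from the input prefix up to t (plus the convolutions'
few-sample lookahead), which limits how much of the observed phase the early
forecast steps can use.

**seq2seq_lstm** — an encoder LSTM summarizes the observed half into its
final hidden/cell state (the context vector).  The decoder LSTM starts from
that state and receives, at every step, the context vector tiled across time
together with the previous output sample; the first step uses the last
observed sample as start token.  A linear head maps decoder states to
channels.

**seq2seq_lstm_pe_ma** — the observed half is embedded to width 96 by a 1-D
convolution and tagged with sinusoidal positional encoding
(PE(pos, 2i) = sin(pos/10000^(2i/d)), PE(pos, 2i+1) = cos of the same
argument); a two-layer LSTM encoder returns full sequences.  The two-layer
decoder continues from the encoder states, its inputs being the tiled
context plus the embedded previous sample plus positional encoding (offset
by the input length).  Multi-head self-attention (16 heads) runs over the
decoder state sequence; its output is added residually to the decoder states
before the linear head.  Width 96 is the nearest attention-divisible width
to the recurrent sizing used elsewhere (16 heads do not divide 100).

The decoder self-attention is **causally masked**.  Rationale: at inference
the decoder is autoregressive (each predicted sample is fed back), so
attention at step t can only exist over steps ≤ t; masking training-time
attention the same way makes training and inference compute the same
function, and the incremental attention cache at inference provably matches
the masked full-sequence pass.  An unmasked reading would make feedback
decoding through the attention layer ill-defined.

### Training

Teacher forcing with MSE loss and Adam; defaults follow the full-scale
regime (learning rate 3e-4, batch 25, 240 passes).  Two stabilizers:

* **Teacher-forcing input noise** (σ = 0.05 by default, 0.15 in reduced
  runs): Gaussian noise added to the fed-back samples during training, so
  the decoder tolerates its own prediction errors at inference.  Without
  it, autoregressive roll-outs drift: training loss falls while held-out
  autoregressive correlation stays near zero (exposure bias).
* **Gradient-norm clipping** at 5.0, the usual guard for backpropagation
  through 256 time steps.

Training without teacher forcing is available; the feedback path is then
treated as constant during backpropagation (stop-gradient), the standard
approximation.

When a validation set is supplied, autoregressive validation correlation is
scored every 10 passes and the best-scoring parameters are restored at the
end.  This matters because autoregressive quality fluctuates substantially
across passes even as teacher-forced loss declines monotonically; selecting
the best checkpoint (on validation data, never test) removes the dependence
on exactly where training stops.  The pipeline carves the chronologically
last 15 % of each class's training pairs into this validation set.

## Classifier

Two Bi-LSTM layers (64 and 32 units; forward and time-reversed passes
concatenated), the second returning only its final concatenated state, then
ReLU → dense hidden layer (352 neurons) → softmax over 5 classes.  Temporal
pooling by final state matches the dense sizing; ReLU sits between the
recurrent stack and the hidden layer.  Training: Adam, categorical
cross-entropy, defaults learning rate 5e-4, batch 10, 240 passes.  The
classifier is always trained on *measured* future halves; forecasts are only
ever classifier *inputs* at evaluation time.

## Neural-network core

No deep-learning framework is used: layers (dense, 1-D convolution, LSTM,
Bi-LSTM, dropout, multi-head attention), losses, and Adam are implemented
directly in NumPy with hand-derived backward passes.  Every layer's analytic
gradient is validated against central finite differences in the test suite
(relative error < 5e-6), including the gradients that flow through the
encoder-to-decoder state handoff.  LSTM input projections are computed once
per sequence as a single matrix product; the per-step recurrence loops in
Python over 256 steps with vectorized batch arithmetic.  Initialization:
Glorot-uniform input weights, orthogonal recurrent blocks, forget-gate bias
1.  All randomness (initialization, batch shuffling, dropout, teacher-forcing
noise) derives from one integer seed, making every training run exactly
reproducible.

## Synthetic data

The generator emulates what the pipeline needs from real wearable-IMU data
without shipping any: per activity, a harmonic series (multiples 1, 2, 3
with relative amplitudes 1, 0.45, 0.2) at a characteristic gait frequency,
per-channel gains and phases, additive Gaussian noise (σ = 0.05 of unit
amplitude by default), and NaN/outlier injections at PAMAP2-like rates
(10⁻³ and 5·10⁻⁴ per sample).  Fundamentals are 1.4, 1.9, 2.4, 2.9, 3.4 Hz
for walk, Nordic walk, stairs ascend, stairs descend, run — the cadence
*ordering* of the real activities, spaced widely enough that a spectral-peak
oracle classifies epochs near-perfectly, which certifies that the corpus is
learnable and separable by construction.

Two features make the signals quasi-periodic rather than strictly periodic,
as real gait is: the instantaneous rate and the amplitude envelope each
follow an Ornstein-Uhlenbeck process (relative SD 2 % and 8 %, correlation
time 2 s) — values in the range of reported stride-time and amplitude
variability for steady locomotion.  Without this variability a direct
input-to-output map can saturate the forecasting task by phase lookup, and
the comparison between forecaster architectures degenerates.  Each scheduled
activity block also draws random channel phases so models cannot memorize
absolute time.

What the generator does **not** emulate: non-stationary activity
transitions, gravity orientation drift, sensor-axis cross-talk, subject
heterogeneity, and the broadband impact transients of real footfalls.
Passing tests on this corpus therefore demonstrate that the pipeline's
machinery works end to end on learnable quasi-periodic multichannel
signals — not that the specific published accuracies on any real benchmark
are reproduced.

## Scale of the shipped experiments

The test suite and the acceptance script run a reduced configuration chosen
as a deliberate CPU-scale design point: 32-unit LSTMs, embedding width 32,
4 attention heads, 25 epochs per class (≈ 100–125 pairs), 60–200 training
passes at learning rate 3e-3, teacher-forcing noise 0.15.  The architecture
comparison trains all three forecasters on the same corpus and seeds (three
seeds) and compares mean held-out correlation; the end-to-end check trains
the classifier at reduced size (16/8 Bi-LSTM units, 64 hidden neurons,
30 passes) and compares classification of measured versus forecasted future
halves.  Full-size defaults remain available through the specs and configs.

## Numerical choices and degenerate inputs

* Attention logits are shifted by their row maximum before exponentiation;
  weight rows sum to 1 within 1e-6 by construction.
* Pearson correlation raises on zero-variance input rather than returning a
  silent 0; validation scoring treats such early-training forecasts as
  score 0.
* An all-constant recording normalizes to zeros with a warning.
* Per-class precision/F1 with no predicted positives is reported as 0.
* Forecast values are clipped to [-1, 1] only when fed to the classifier
  (whose training domain that is); forecast metrics use unclipped output.
* Moving-average edges use shrinking windows (output length preserved);
  'same'-padded convolutions pad (k-1)//2 left and k//2 right.

## Known limitations

* Training at full published scale (256-unit LSTMs, 2283 epochs, 240
  passes) is possible but slow in pure NumPy; the shipped experiments use
  the reduced design point above.
* The plain sequence-to-sequence and attention variants differ only
  modestly on this corpus at reduced scale; the conv2lstm gap is the robust
  part of the architecture ordering.
* The classifier's reduced configuration trades accuracy for runtime; its
  full-size defaults follow the published architecture.
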