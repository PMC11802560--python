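# Methods

## Problem and approach

`sefcn` detects epileptic seizures in multi-channel scalp EEG and, beyond
the binary decision, attributes the detection to individual electrodes.
The classifier is a fully convolutional network (FCN) over 2-s epochs
with a squeeze-and-excitation (SE) channel gate; the attribution comes
from the network's own upsampling path: the final transposed-convolution
layer restores a score map at the input's full time resolution, one row
per electrode, which is normalized into a channel-weight matrix.

Evaluation is patient-independent throughout: leave-one-patient-out
(LOPO) cross-validation, in which each patient's data is scored by a
model that never saw that patient during training.

## Preprocessing

Recordings (256 Hz, bipolar 10–20 montage, microvolts) pass through:

1. **Bandpass** — 6th-order Butterworth, 1–60 Hz, applied
   forward–backward (zero phase, `sosfiltfilt`). Zero-phase filtering
   keeps epoch boundaries aligned with annotations; the effective
   magnitude response is the square of the designed 6th-order prototype.
2. **Resampling** to 128 Hz (polyphase FIR, anti-aliased). Annotations
   are stored in seconds and are unaffected.
3. **Epoching** into 2-s windows (256 samples). The default stride
   equals the window (non-overlapping); any stride is supported. A
   trailing remainder shorter than one window is dropped.
4. **Channel padding** to a fixed 32-row canonical layout: 23 bipolar
   derivations (CHB-MIT-style montage) followed by all-zero rows named
   `PAD_0…PAD_8`. Fixed geometry lets one trained network serve any
   record whose channels are a subset of the canonical list.
5. **Labeling** — an epoch is ictal (label 1) iff its half-open window
   `[start, start+2)` overlaps a seizure interval `[onset, offset)` by
   any positive amount. The rule is deliberately permissive; with 2-s
   epochs the label noise it can introduce is at most one epoch per
   seizure boundary.

## Architecture

Input is one epoch shaped 32 rows × 256 samples. All kernels are
`(1, k)` — they slide along time only, so electrode rows share weights
but do not mix until the dense head. Downsampling path: three
convolutions (32, 64, 128 filters; kernel (1,4), stride (1,2)), batch
normalization + ReLU after the first two, ReLU after the third
(configurable), then the SE gate. Upsampling path: a 1×1 score layer to
2 channels followed by three transposed convolutions (kernel (1,4),
stride (1,2), each exactly doubling the time axis), with FCN-style skip
fusion: 1×1 score projections of the first and second convolution
stages are added element-wise to the first and second upsampled maps.
Element-wise addition of same-shaped 2-channel score maps is the only
fusion consistent with the layer shapes; it is the FCN-8s convention.
The final 32 × 256 × 2 map is flattened (16 384) into a single dense
layer producing 2 logits → softmax.

The SE gate computes, per feature map `U` with C filter channels:
`z_c = mean_{i,j} u_c(i,j)` (squeeze), `s = σ(W₂ δ(W₁ z))` with
reduction ratio r = 8 (excitation, no biases), and `x̌_c = s_c · u_c`
(scale). It is a per-channel scalar gain, verified as such by a
property test. The attention stage is pluggable (`attention="identity"`
ablates it) behind the same shape contract.

The network is implemented directly in NumPy with hand-derived
backpropagation (im2col convolutions backed by BLAS matrix products;
float32 by default, float64 available). Every layer's gradient is
pinned against central finite differences in the test suite. Training
uses Adam (lr 1e-3), softmax cross-entropy, batch size 32; the
checkpoint with the highest validation accuracy across training epochs
is the one evaluated; accuracy ties are broken by the lower validation
loss, since on separable data several checkpoints reach the same
accuracy but the later, lower-loss ones are better calibrated around
the 0.5 decision threshold. Inputs are
standardized by the training set's global mean/std, stored with the
model. Training batches are augmented with two label-preserving
transforms: a random polarity flip — the sign of a bipolar derivation
is a montage convention, and without this the dense head can overfit
the discharge polarity of individual training patients — and a random
circular time shift, since epoch alignment is arbitrary under
sliding-window segmentation. The learning rate, optimizer, head depth and class weighting are
this package's choices; only batch size, epoch budget and
best-validation selection are fixed by the protocol being reproduced.

## Evaluation protocol and metrics

`lopo_splits` builds one fold per patient; within a fold a seeded
random 20% of the non-test patients' epochs is validation, 80%
training. The validation draw is by epoch (a by-record option would
avoid leakage between temporally adjacent epochs; at the default
non-overlapping stride adjacent epochs share no samples).

Metrics per held-out patient: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), G-Mean √(SEN·SPE), accuracy, AUC (rank statistic, ties ½ —
tested against exhaustive pair enumeration), and detection latency
(time from seizure onset to the start of the first predicted-positive
epoch within the event; undefined if the event is never flagged). Rates
with zero denominators are reported as NaN, never coerced.

The summary row reports per-column mean ± SEM (sd/√n over patients),
except G-Mean: the summary G-Mean is √(mean SEN × mean SPE), the
geometric mean of the column means, matching the convention of the
published benchmark table this package uses in its worked examples.
(Note: that table's printed SEM values are far smaller than the
dispersion of its own per-patient columns implies; this package always
computes SEM from the rows it is given.)

## Interpretability

For a 20-s window (10 contiguous epochs) the seizure-class slice of
each epoch's final deconvolution map is concatenated in time, giving a
32 × 2560 matrix `b` (channels × time; published descriptions of the
same object sometimes print it transposed). The weight matrix is the
max-abs row normalization

    C[i, j] = |b[i, j]| / max_j |b[i, j]|,

mapping each row into [0, 1] with its maximum at exactly 1; all-zero
rows (padding) map to zero and are excluded from rankings. A channel's
score is the time-mean of its row (max and 95th-percentile are offered;
the mean is the default because it rewards sustained rather than
isolated activation). Channels are ranked descending, ties broken by
canonical order, and bipolar labels are mapped to their two 10–20
electrodes and cortical regions.

Because convolutions act along time only, a row of the final map is a
function of that row's input signal alone (batch statistics and SE
gains are shared scalars), which is what makes per-row comparison
meaningful. Row normalization removes absolute amplitude differences
between rows; discrimination comes from the *shape* of each row's
activation — rows driven by a sustained ictal rhythm have a high
mean-to-peak ratio, background rows a low one.

Whether the window should start at seizure onset (ictal) or end at it
(pre-ictal) is genuinely ambiguous in published usage; both are
supported (`pre_onset=True`), the default is ictal.

## Synthetic data

The generator emulates the statistical skeleton of a CHB-MIT-style
recording: per-channel pink noise (1/f, RMS 30 µV) plus a 10-Hz alpha
sinusoid (10 µV) for background, and seizures as a harmonic-rich 2–6 Hz
spike-wave surrogate (five 1/h-weighted harmonics) confined to a chosen
channel subset, scaled to `amplitude_gain` × background RMS and
crossfaded over 0.5 s inside the annotated interval. Cohorts derive
per-patient seeds from one root seed (SeedSequence), so generation is
bit-reproducible.

What it does **not** model: artifacts (blinks, EMG, electrode pops),
16-bit quantization, inter-channel correlation of background activity,
evolving seizure morphology and propagation, or patient-specific
spectra. Passing the recovery experiment therefore shows the pipeline
is correct and sensitive under clean, known conditions; it does not
predict clinical performance on real EEG, where the published benchmark
numbers (mean G-Mean ≈ 0.83 over 23 patients) indicate the task is far
harder.

## The recovery experiment (study conditions)

Four synthetic patients, 80-s records, one 24-s seizure (onset 30 s) on
channels 3 and 7 (P7-O1, P3-O1) with amplitude gain 6 and a 3-Hz
rhythm; full LOPO with 8 training epochs per fold; interpretability on
the 20 s from onset, aggregated across the four fold reports (mean
channel score); five replicate cohorts from derived seeds. Success per
seed = the two injected channel rows occupy the top-2 ranks. The sizes
were chosen once so that a full five-seed replication runs in minutes
on a single CPU while every stage still operates at its native
geometry (32 × 256 inputs, 20-s windows).

## Numerical notes and limitations

* Transposed convolutions use kernel (1,4), stride (1,2), padding 1,
  output width exactly 2× input — a tested contract; input widths must
  be divisible by 8.
* Batch normalization uses batch statistics in training and running
  (momentum 0.9) statistics at inference; ε = 1e-5.
* The sigmoid is evaluated in a numerically stable two-branch form;
  softmax is max-shifted.
* Float32 arithmetic makes training runs reproducible on a given BLAS
  but not necessarily across BLAS implementations; all non-training
  stages are exactly deterministic.
* The EDF writer emits 1-s data records and zero-pads to whole seconds;
  per-channel physical scaling bounds quantization error at one part in
  32 767 of each channel's peak amplitude.
* Only the SE attention block is implemented; the block interface
  accepts alternatives but none are provided.
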