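# Methods

## Problem and model

The package decodes motor-imagery classes (e.g. left- vs right-hand
imagined movement) from short multi-channel EEG windows, in the
cross-subject setting where windows from all subjects are pooled. The
classifier is a multi-branch fusion convolutional network: several
EEGNet-style branches receive the identical `(C, W)` input window and
their flattened feature maps are concatenated ("fused") before a single
softmax head.

Each branch applies, in order:

1. **Temporal convolution** — `F1` kernels of shape `(1, k_t)` with
   length-preserving padding; acts as a learned frequency filter bank.
2. Batch normalization.
3. **Depthwise spatial convolution** — kernel `(C, 1)` with depth
   multiplier `D`, no padding across channels; learns one spatial
   pattern per temporal filter. A unit max-norm constraint over the
   channel axis regularizes these spatial filters.
4. Batch normalization → ELU → average pooling `(1, p1)` → dropout.
5. **Separable convolution** — depthwise `(1, k_s)` temporal kernels
   followed by a pointwise mix to `F2` maps; length-preserving padding.
6. Batch normalization → ELU → average pooling `(1, p2)` → dropout →
   flatten.

The five-branch default uses `F1 = (8, 16, 32, 64, 128)`,
`k_t = (64, 80, 96, 112, 128)`, `F2 = (16, 32, 64, 128, 256)`,
`k_s = (8, 16, 32, 64, 128)`, dropout 0.5. Five alternative temporal
kernel-length sets (`test_config_spec(1..5)`) reproduce the published
filter-size study; variant 4 is the adopted default. The per-branch
feature dimension is `F2 * floor(floor(W/p1)/p2)`; for `W = 80` windows
the fused dimension is 992.

Terminology is normalized to the EEGNet convention: scalar "kernel
sizes" in the source description are filter *counts* (`F1`, `F2`) and
`(1, k)` "filter sizes" are kernel *shapes*. Hyperparameters the source
architecture leaves implicit are fixed at the EEGNet defaults —
`D = 2`, `p1 = 4`, `p2 = 8`, max-norm 1.0 on the depthwise spatial
kernels, no bias on convolutions, bias (and no norm constraint) on the
dense head, ELU after the depthwise and separable stages but not after
the first temporal convolution. All are configurable per branch.

## Numerical engine

No deep-learning framework is used: the layers, their backward passes
and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) are implemented in
numpy/scipy (`eegfusion.nn`), in float32 with layout
`(batch, channel, time, feature)`. Temporal convolutions (and their
gradients) are evaluated with FFT convolution along the time axis, so
kernels longer than the window (e.g. `k_t = 1024` at `W = 80`) cost
O(T log T). "Same" padding follows the stride-1 convention
`pad_left = (k-1)//2`, `pad_right = k//2`. Batch norm uses ε = 1e-3 and
momentum 0.99 on the moving statistics, which are checkpointed together
with the weights. Initialization is Glorot-uniform from one seeded
generator per model; dropout draws from the same generator hierarchy.
The analytic gradients of every layer are verified against centered
finite differences in double precision in the test suite.

Argmax ties at prediction time resolve to the lowest class index.
Division-by-zero in precision/recall/F1 yields 0 with a warning.

## Preprocessing

The 160 Hz recipe filters the continuous recording (not the epochs, to
keep edge transients away from 80-sample windows): a 60 Hz notch
(quality factor Q = 30 by default; only the frequency is prescribed by
the source protocol) followed by a 2–60 Hz Butterworth band-pass of
order 5. Both are applied zero-phase (forward–backward), a choice made
because the pipeline is offline and group delay would shift epoch
alignment. Epochs of 4 s (640 samples) start at each task annotation
(rest annotations are excluded by omission from `keep_labels`); each is
partitioned into eight non-overlapping 80-sample windows that inherit
the epoch label. The 250 Hz session recipes cut 4.5 s epochs (1125
samples) starting 1.5 s after the cue and rely on the source records'
native 0.5–100 Hz band-limit; standardization (per-channel z-scoring
with training-partition statistics only) replaces re-filtering there.
Sample indexing is 0-based with half-open intervals; trailing partial
epochs or windows are dropped and logged, never padded.

Six subjects of the 109-subject PhysioNet motor imagery corpus
(38, 82, 88, 89, 100, 104) carry inconsistent annotations and are
excluded, leaving 103; at 45 trials × 8 windows this yields 360 windows
per subject and 37,080 in total.

## Training protocol

Pooled windows are split 70/10/20 (train/validation/test) by a
seed-determined uniform permutation; partition sizes are
floor-of-fraction with the remainder assigned to training (37,080 →
25,956 / 3,708 / 7,416). Session-structured datasets instead use
`session_split` (whole sessions in either train or test). After each
epoch the validation accuracy is evaluated in inference mode; weights
are checkpointed on improvement (first occurrence wins ties) and the
best checkpoint is restored before evaluation, so re-evaluating the
validation set reproduces the recorded maximum exactly.

Defaults follow the published protocol: Adam with learning rate 1e-5
and binary cross-entropy (element-wise on the softmax outputs, averaged
over samples and classes). Binary cross-entropy is ill-defined as a
training target for more than two mutually exclusive classes, so
4-class configurations use categorical cross-entropy. Batch size (16)
and epoch budget (100) are not prescribed anywhere and are free
parameters.

## Synthetic data

The generator emulates event-related desynchronization (ERD), the
physical signature motor-imagery decoders exploit: a narrow-band
rhythm (default mu, 8–12 Hz, amplitude 2 µV) rides on 1/f-shaped
background noise (unit variance) plus white noise (`noise_std`, default
1 µV). During a trial of class *k* the rhythm amplitude on the *k*-th
contiguous channel block is scaled by `1 − erd_depth`; blocks are a
round-robin split of the channels (halves for two classes). The rhythm
frequency and phase are redrawn per trial so the class cue is carried
by band power, not by phase. Defaults mirror one PhysioNet-style run:
64 channels, 160 Hz, 45 four-second trials, two classes, 4 s
inter-trial gaps.

What the generator does **not** model: volume conduction and realistic
spatial mixing, artifacts (EOG/EMG), non-stationarity across a session,
inter-subject variability of rhythm frequency and topography.
Consequently, passing the learnability checks shows the pipeline and
optimizer are correct, not that published accuracies on real EEG are
reproduced — those require the three public datasets and long GPU
training and are out of scope here.

## Problem sizes used in the checks

The structural cohort check runs the full 103 synthetic subjects at the
native 64-channel geometry. The learnability demonstrations use a
reduced geometry chosen to be decodable yet cheap: 8 channels, 60
trials (480 windows of 8×80), `erd_depth` 0.8, `noise_std` 0.5, and the
five-branch default model trained for 8 epochs at learning rate 1e-3
(the published 1e-5 is tuned for very long training schedules; at desk
scale it barely moves the weights, so the demonstration uses a rate
that converges within a few epochs — the library default remains 1e-5).
The no-signal control (`erd_depth = 0`) trains at the default 1e-5 for
5 epochs and must stay within 3 binomial standard deviations of chance.

## Known limitations

- Single-threaded CPU training; practical for hundreds of windows, not
  for the full 37,080-window cohort at 64 channels.
- The EDF+ writer supports continuous (EDF+C) 16-bit records with
  integral samples-per-record only; physical range is chosen
  symmetric per file, not per channel.
- Random splits operate at window level, as in the source protocol;
  windows of one trial can land in different partitions, which inflates
  absolute accuracy on strongly autocorrelated data. Use
  `stratify_by`/`session_split` when that leakage matters.
- Only the five-branch configuration ships as a named preset (in its
  five kernel-length variants); other branch counts are expressible
  through explicit `BranchSpec` lists or by slicing the default's
  `branches` tuple.
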