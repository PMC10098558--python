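# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `imuhar`. It is the package's own account of what it
computes; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Problem setting

Infant movement is recorded by four limb-worn IMUs (proximal left/right arm
and leg placements) streaming triaxial accelerometer (m/s², range ±8 g) and
gyroscope (deg/s, range ±500) samples at a nominal 52 Hz over Bluetooth, in
packets of four consecutive samples. Each ~half-second of a recording is
annotated with one of seven movement categories (Still, Proto movement,
Turn left/right, Pivot left/right, Commando crawl), heavily skewed toward
Still. The task is frame-wise 7-class classification.

## Preprocessing

1. **Interpolation.** Packet timestamps are jittered; each sensor is
   linearly interpolated onto an ideal uniform 52 Hz grid. All four sensors
   share one grid spanning the intersection of their time ranges, anchored
   at the latest first-timestamp; no extrapolation beyond recorded data.
2. **Gyro bias.** Each gyroscope channel's constant bias is estimated as
   the mean of the 64-sample contiguous segment with minimal variance (the
   quietest stretch) and subtracted. Ties in the variance scan go to the
   earliest segment.
3. **Median filter.** Every channel is 5-sample median filtered. At the
   recording edges the window shrinks symmetrically (widths 1 and 3) so no
   data outside the recording is invented.
4. **Windowing.** The (24, N) matrix — channels ordered sensor-major
   (LA, RA, LL, RL) × (acc xyz, gyro xyz) — is cut into 120-sample (2.3 s)
   frames with 50% overlap (hop 60). A trailing remainder shorter than one
   frame is discarded.

The order interpolate → bias → median follows the pipeline description
read in sequence; the bias estimate is insensitive to the 5-sample median
since it averages 64 samples.

## Architectures

Every system is encoder + temporal head, trained jointly.

**Encoders** map a (24, 120) frame to a bottleneck vector (default 160):

| kind | fusion strategy | parameters |
|---|---|---|
| `dense` | flatten 2880 → FC 256 (tanh) → 256 → 256 → 160 | ~950 k |
| `conv1d` | channels fully connected into filters; 4 conv layers k=5 s=2, widths 64/64/96/96; FC to 160 | ~230 k |
| `conv2d_i` | separate acc/gyro paths; (3×5) s(3,2) xyz-fusion then (4×5) s(1,2) sensor-fusion convs; two 1-D convs; 2 FC mixing layers | ~235 k |
| `conv2d_is` | `conv2d_i` + a shared path whose xyz-fusion filters are tied across modalities | ~352 k |
| `conv2d_si` | one shared per-sensor module (acc/gyro/shared paths on a 6×120 block), applied to all 4 sensors with identical weights, no intersensor mixing; outputs concatenated | ~46 k |

Hidden widths are this package's choices (the family fixes only the fusion
topology): the flattened 2880 → 256 dense entry point is given, conv paths
use 32 channels, post-fusion 1-D convs use kernel 5 stride 2, mixing FC
width 256. Activations are LReLU (slope 0.01) except the dense encoder's
hidden tanh layers; bottleneck layers are linear. "Half" zero-padding makes
stride 2 exactly halve the time axis (120→60→30→15→8, ceil). Weights are
uniform fan-in initialized from a seed.

Because `conv2d_si` shares one submodule across sensors, its parameter
count is independent of the sensor count and permuting the four input
sensor blocks permutes the four output feature blocks identically — both
properties are tested.

**Temporal heads** map the (T, D) bottleneck sequence to per-frame
softmax probabilities: `dense` (frame-wise FC, no temporal modeling),
`lstm`/`gru` (unidirectional, hidden 160, causal), `bgru` (forward +
backward GRU concatenated), and `wavenet` — four gated dilated-convolution
blocks (dilations 1, 2, 4, 8, kernel 5, 64 residual/skip channels;
tanh ⊙ sigmoid gating, 1×1 residual and skip projections, skip-sum head).
The dilated stack's receptive field is 1 + (k−1)·Σd = 61 frames ≈ 69.2 s
(verified by a perturbation test). Convolutions are centered, since
classification is offline; a causal mode is available by flag. Recurrent
hidden sizes match the bottleneck width; these are package choices.

Sequences are processed in minibatches of 100 consecutive frames with zero
initial state and no carry-over, in training and inference alike.

## Augmentation

Input dropout (`dr1`) and bottleneck dropout (`dr2`) use inverted dropout
at p = 0.3 (scaling survivors by 1/(1−p)) so inference needs no
compensation. Sensor dropout (`drs`): with p = 0.3 one uniformly chosen
sensor is zeroed for the whole minibatch. Rotation (`rot`): per sensor per
minibatch, R = Rz(α)Ry(β)Rx(γ) with angles uniform in ±10°, multiplying
both triads. Time warp (`tw`): per frame, the local sampling interval is
modulated by 2 + A·sin(2πωt + 2πφ) with A, ω, φ ~ U[0, 1], integrated,
rescaled to the original frame duration (neutralizing the additive 2) and
linearly resampled to 120 samples. Operators compose in the fixed order
rot → tw → dr1 → drs; all are identity at evaluation.

## Training and evaluation

Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), frame-wise cross-entropy against hard or
soft labels, minibatches of 100 consecutive frames of single recordings,
up to 250 epochs with early stopping on validation loss (patience 30,
best-epoch weights restored). 20% of each recording's blocks are held for
validation; when recordings are so short that the per-recording share
rounds to zero, the selection is topped up across recordings until the
global 20% is met — otherwise validation monitoring degenerates to a
single block and model selection becomes noise.

The metric is the unweighted average F1 (UWAF): per-class
F1 = tp/(tp + 0.5(fp+fn)), averaged over classes. Classes absent from both
truth and predictions are excluded from the average rather than scored 0,
so a dataset slice that simply lacks a rare class does not zero the score;
exclusions are visible in the per-class report (NaN). Cross-validation is
subject-disjoint k-fold (default 7) with seeded random partition, repeated
(default 3×) and averaged. Uncertainty is a percentile bootstrap over
recording-level UWAF (default 10 000 resamples); module comparisons use
the two-sided Wilcoxon rank-sum test (exact below n = 25 without ties,
mid-rank normal approximation otherwise).

Robustness conditions: sensor dropout (1 or 2 sensors zeroed; every
combination evaluated and averaged) and packet loss (4-sample packet-
aligned bursts zeroed per sensor until the requested fraction, applied to
the preprocessed tensor; 25% moderate / 50% severe; five seeded
repetitions averaged).

## Synthetic data

The real dataset is not public, so the generator produces recordings with
the same plumbing and a deliberately simple signal model: per-sample labels
follow a Markov chain whose stationary distribution matches configured
priors (defaults reproduce the real data's skew, Still ≈ 59% of frames)
with geometric dwell times (default self-transition 0.999 ≈ 19 s mean
dwell); each limb's accelerometer is a slowly drifting gravity vector plus
a class/limb-specific sinusoid plus noise, the gyroscope a class/limb
sinusoid plus constant bias plus noise; samples are packetized in fours
with jittered timestamps (σ = 2 ms, well under half the 19.2 ms period).
Gravity directions start at fixed per-limb mount poses with a bounded
posture spread (default ±25°) — sensors are sewn into a garment, so
orientation is not arbitrary across recordings — and drift slowly.
Classes differ by which limbs move and at which frequency/amplitude
(e.g. Still: none; Proto: all limbs at 0.9 Hz; Turn L/R: lateralized at
1.6 Hz; Pivot L/R: leg-dominant at 2.4 Hz; Crawl: all limbs at 3.6 Hz),
which makes them separable by construction.

What the generator does **not** emulate: real infant kinematics and their
within-class diversity, annotator ambiguity at category boundaries,
posture-dependent signal coupling, hardware dropouts in the raw stream.
Tests passing on this data therefore validate the pipeline's mechanics and
learning dynamics — not clinical performance; absolute UWAF values on real
recordings (which peaked near 0.75–0.8 for the best systems at ~10× more
data) are out of reach of any synthetic stand-in and are not claimed.

The `easy_benchmark` preset (8 recordings × 3 min, balanced priors, low
noise) is the dataset used by the end-to-end sanity checks: the best
system (sensor-independent encoder + dilated-convolution head) must reach
UWAF ≥ 0.9 on held-out recordings while a label-shuffled control stays at
chance, and sensor-dropout-augmented training must improve the
one-sensor-dropped condition without losing clean performance. The
end-to-end checks train at reduced scale — 60-epoch cap with patience 15
(100/25 for augmented training, which converges more slowly) — and
a 32-channel dilated-convolution head: model capacity is matched to a
dataset roughly 25× smaller than the real one, where the full-width
64-channel head has enough capacity to memorize training label-sequence
context instead of transferable structure (train/holdout UWAF 0.98/0.62
at width 64 versus 0.96/0.97 at width 32 under identical conditions).
These sizes are stated here as the package's chosen benchmark conditions;
the package default remains 64.

## Numerical core

No deep-learning framework is a dependency: `imuhar.nn` is a compact
reverse-mode autodiff on NumPy arrays (float64) with exactly the
primitives the architectures need — im2col-style `unfold` turning
convolutions into single GEMMs, gating nonlinearities, fused
softmax/cross-entropy — plus Adam. Gradients of every layer type are
verified against central differences (~1e-9 max error) in the test suite.
Determinism: all initialization, minibatch order, augmentation and
simulation randomness derive from explicit seeds via NumPy `SeedSequence`;
the same seed reproduces a training run bit-for-bit on the same BLAS.

## Known limitations

* Recurrent layers process one sequence at a time (no batched sequences);
  RNN training is correspondingly slow and is exercised only at small
  scale in the tests — mirroring, at miniature scale, the 6:1 RNN/non-RNN
  training-time ratio the architecture comparison reports.
* The packet-loss simulator zeroes samples post-preprocessing; it does not
  model interpolation across gaps in the raw stream.
* The `dense`/`conv` hidden widths are plausible defaults, not recovered
  values; parameter-count comparisons are meaningful directionally
  (conv1d < dense, conv2d_si smallest) rather than as absolute replicas.
* Exact-enumeration Wilcoxon applies below n = 25 without ties; with ties
  the normal approximation is used at any n.
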