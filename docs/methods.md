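# Methods

## Problem and pipeline

The package classifies sagittal-view walking sequences, given as binary
silhouette frames, into five gait classes: normal, diplegic, hemiplegic,
neuropathic and parkinsonian. The pipeline is

1. optional mirroring of right-to-left sequences to a canonical
   left-to-right orientation, and optional silhouette cleaning (largest
   4-connected component, hole filling);
2. gait-cycle segmentation from the feet-distance signal;
3. selection of 9 key frames per cycle at fixed cycle fractions;
4. per-frame spatial feature extraction with a truncated convolutional
   backbone, fine-tuned on key frames;
5. temporal fusion with a bidirectional LSTM and dense softmax
   classification, one decision per gait cycle.

The central modelling assumption is that pathological signatures live
both in per-frame posture and in the *order* of postures across the
cycle; the BiLSTM is the component that exploits the order, and the
temporal-sensitivity test (shuffling the key-frame order at test time
degrades accuracy) verifies that it actually does.

## Cycle segmentation

The feet-distance signal is the horizontal span (max column − min
column) of foreground pixels in the bottom band of the silhouette
bounding box. Measurement choices, all exposed as parameters:

- `band_fraction` = 0.15 — tall enough to include both feet through
  ankle flexion, short enough to exclude the knees;
- `smooth_window` = 5 frames, centred moving average, edge-truncated.
  Because truncation biases the first/last samples low, boundary-peak
  qualification consults the unsmoothed signal (kept on the signal
  object);
- peak prominence ≥ 0.2 × signal range, separation ≥ 0.25 × the
  autocorrelation-estimated period; plateau peaks report the plateau
  centre (ties to the lower index);
- boundary samples may qualify as peaks when they are within 20% of the
  signal range of the maximum — walking clips routinely start and end
  at double support, and rejecting endpoints would drop the first and
  last cycle. A sequence that stops mid-rise is not given a spurious
  end peak by the same rule.

Cycles are spans between three consecutive peaks, paired disjointly
(peaks 0-1-2, 2-3-4, ...); an unpaired trailing peak is unused. Cycle
detection runs on the raw-geometry masks — height/centroid alignment
would erase the signal — but, deviating from a strict "untouched input"
reading, the pipeline by default applies silhouette cleaning *before*
detection: cleaning removes exactly the spurious-blob corruption that
otherwise inflates the bottom-band span, and is the package's principal
robustness mechanism against segmentation errors. `PipelineConfig.clean`
turns it off.

Key-frame fractions are fixed at (0, .12, .24, .36, .48, .60, 11/15,
13/15, 1): the stance/swing transition is pinned at the healthy-gait
60% constant for every class, the stance is divided into five equal
portions and the swing into three. Fractional indices are rounded half
up. Cycles spanning fewer than 9 frames are rejected rather than padded.

## Silhouette normalization

Before feature extraction or energy-image averaging, each silhouette is
isotropically rescaled (nearest neighbour, edge samples pinned so the
resampled box stays tight) to make its height 0.9 × canvas side, placed
bottom-anchored at the canvas bottom margin with the foreground centroid
on the centre column. This is the conventional energy-image alignment;
the operation is idempotent, which makes re-processing safe.

## Network stack

No deep-learning framework is used; `gaitpath.nn` implements the needed
layers on float32 NumPy arrays with explicit backprop: 3×3 same-padding
convolution (im2col), 2×2 max pooling, dense, inverted dropout, LSTM
with backpropagation through time, softmax cross-entropy and the Nadam
optimizer (Adam with Nesterov momentum; β₁ = 0.9, β₂ = 0.999). Gate
order in the LSTM is (input, forget, cell, output) with forget bias 1.
Conv/dense weights use He-uniform initialization, LSTMs Glorot-uniform.
Final classification layers are zero-initialized: an untrained head
outputs exactly uniform probabilities, and training becomes exactly
equivariant to a relabelling of the classes at a fixed seed.

Backbones:

- `vgg16` — 13 conv layers in 5 blocks (64, 64, 128, 128, 256×3,
  512×3, 512×3), each block followed by 2×2 pooling; flatten; one
  4096-unit dense layer as the truncation point. Binary masks are
  replicated to 3 input channels. Pretrained weights are an optional
  external asset; everything here runs from random initialization.
- `compact` — 3 single-conv blocks (8, 16, 32 channels), flatten, dense
  `feature_dim`. Same interface, sized for CPU experiments.

Fine-tuning (stage 1) stacks dense(`feature_dim`) + softmax(`n_classes`)
on the trunk, trains on individual key frames labelled with their
sequence's class, and freezes the first `frozen_blocks` conv blocks
(default 2, verified bit-exactly by tests). Freezing protects
pretrained low-level filters; when the backbone is randomly initialized
there is nothing to protect, so compact-mode end-to-end runs set
`frozen_blocks = 0`.

Stage 2 trains the BiLSTM (9 steps per direction; final hidden states
concatenated: 2 × `lstm_units`, 512 at the default 256) plus FC-512 →
dropout 0.5 → FC-5 on the extracted, frozen feature sequences. The two
stages are trained separately; no joint end-to-end gradient is taken.

Defaults follow the reference configuration: learning rate 1e-4,
dropout 0.5, 256 LSTM units, 5 classes, frozen blocks 2. Epoch counts
and batch sizes are not externally prescribed; package defaults are 30
epochs, batch 32, and the compact-scale experiment configs in the test
suite use lr 1e-3 (stage 1, 4 epochs) and 3e-3 (stage 2, 120 epochs),
chosen for stable convergence of the small backbone.

## Synthetic gait generator

A planar articulated walker with rigid segments (thigh 0.26 H, shank
0.24 H, torso 0.36 H, arms, feet, head disc for body height H = 100 px)
driven by sinusoidal hip trajectories with the legs in antiphase, a
double-bump knee-flexion profile peaked in swing, and a steppage term
that lifts the swing ankle via extra hip flexion. The hip height is set
each frame so the lowest ankle rests exactly on the ground line. The
silhouette is the union of filled capsules plus a head disc (single
connected component); the skeleton rendering draws the same segment
graph at ~2 px width.

Class presets encode stylized sagittal signatures — normal (symmetric,
upright), diplegic (bilateral stiff knees, lean, short steps),
hemiplegic (stiff left leg), neuropathic (high-stepping, elevated foot
lift), parkinsonian (stooped, shuffling, short quick steps) — each at
two severities, severity 2 strictly further from normal in every
deviating parameter. Subject identity is a ±10% multiplicative
perturbation of every kinematic parameter drawn once per subject from a
per-subject substream; all randomness derives from one master seed via
`numpy` `SeedSequence` key lists, so cohorts are bit-reproducible.

The corruption mode emulates background-subtraction artefacts:
per-pixel Bernoulli flips, Poisson-many small spurious blobs, and
probabilistic 3×3 erosion. The robustness experiments use flip rate
0.004, 1.5 blobs/frame, erosion probability 0.3.

What the generator does **not** emulate: clothing/appearance variation,
perspective and scale changes, camera jitter, self-occlusion artefacts
of real segmentation, out-of-plane motion, and genuinely pathological
biomechanics (the presets are stylized signatures, not clinically
calibrated models — as in the emulated datasets, where healthy subjects
*simulate* the pathologies). Passing the synthetic end-to-end tests
therefore demonstrates that the pipeline recovers class structure from
silhouette dynamics under subject-wise splits; it does not certify
clinical performance on real recordings.

## Evaluation conventions

- Subject-wise folds: fold k tests the subjects at ordinal positions
  (2k−1, 2k, 2k+1), 1-based stride 2 (21 subjects → 10 folds, 18
  training subjects each); train/test subject sets never intersect.
- The evaluation unit is the detected gait cycle; each cycle is
  classified independently. Sequence-level decisions (argmax of the
  mean per-cycle probability vector) are available but not the default
  metric.
- Overall accuracy is *macro*: the mean of the row-normalized confusion
  matrix diagonal, which equals pooled accuracy only on class-balanced
  test sets. Classes absent from a test set are averaged out with a
  warning.
- Sequences flagged as subject repetitions are excluded from
  cross-validation and included in cross-dataset training. Cross-dataset
  evaluation requires disjoint subject namespaces.
- Full precision is reported throughout; no rounding is applied before
  averaging fold matrices.

## Experiment sizes

The compact-scale experiments in the test suite use 16 synthetic
subjects (12 train / 4 test), 5 classes × 2 severities, one walking
direction (direction handling is covered separately by the mirroring
unit tests), 2 gait cycles per sequence, 48 px inputs, 64-d spatial
features and 32 LSTM units per direction, repeated over 3 seeds with the
median reported. These sizes were chosen as the smallest configuration
at which the classes remain cleanly separable and subject identity is
non-trivial.

## Known limitations

- Peak-based segmentation assumes roughly periodic walking; freezing
  episodes or turns would need explicit handling.
- The 60% stance/swing constant is applied to all classes; severely
  asymmetric gaits shift the true transition, and the key frames then
  sample slightly off the named functional phases (by design, matching
  the reference procedure).
- The NumPy network stack is single-threaded-deterministic but not
  performance-competitive with GPU frameworks; `vgg16` mode is provided
  for topology fidelity and works at full input size, but realistic
  fine-tuning throughput calls for the compact backbone.
- SEI inputs must be supplied (or synthesized); no pose estimator is
  included.
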