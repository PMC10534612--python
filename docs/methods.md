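# Methods

This note documents the models, parameter choices and numerical decisions
behind `thermaffect`, and what the synthetic validation does and does not
establish about real thermal recordings.

## The measurement model

A session is a sequence of 8-bit grayscale facial thermograms (brighter =
warmer), one frame per 4 s: ~30 frames for a 2-minute resting baseline,
~75 for a 5-minute task. Emotion-linked autonomic activity changes facial
skin temperature regionally — nasal/maxillary cooling from
vasoconstriction and sweating, forehead warming under stress, cheek
changes tracking valence — so the analysis reduces each frame to
statistics of five ROIs and asks whether those statistics separate
emotional states across participants.

## Synthetic cohorts

The generator is the package's ground-truth instrument, not a physical
simulation. Each participant gets a face template: a bright ellipse
(face) on a dark background, a smooth radial gradient plus a faint
participant-specific sinusoidal texture (so binarization, registration and
co-occurrence statistics all have non-degenerate input), and two hot eye
blobs in the upper half. A session frame is

    template + condition ROI deltas + N(0, noise_sd) noise,

rounded and clipped to [0, 255], then moved by a per-frame rigid transform
drawn uniformly within the motion bounds and resampled nearest-neighbour
(preserving the integer palette). Everything sampled — transforms, ROI
rectangles, SAM ratings — is recorded as ground truth.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_participants` | 24 | emulated study size; one exclusion can be simulated downstream |
| `baseline_frames` / `task_frames` | 30 / 75 | 2 min / 5 min at 4 s per frame |
| `face_size` | 160×160 px | face width D = 120 px keeps every ROI ≥ 18 px in both dimensions, so the largest co-occurrence distance (16 px) has pairs in all four directions |
| `roi_effects` | ±10 (cheeks/nose/maxillary/forehead, see below) | directions follow the reported thermal trends; magnitudes are not published, so ±10 gray levels was chosen once as a comfortably recoverable effect against 2-gray-level sensor noise |
| `noise_sd` | 2 gray levels | modest uncooled-sensor noise |
| `motion_max_translation` / `rotation` | 3 px / 2° | small unrestrained head motion |
| valence rules | U+ conditions draw from {3..5}, U− from {1, 2} | guarantees the valence→label rule recovers the intended polarity of every session |

Default effect directions: positive valence — left cheek +10, right cheek
−8, nose −10, maxillary −10, forehead 0; negative valence — left cheek
−10, forehead +10, others as in positive. The right-cheek value is a
package choice (only its significance, not its printed direction, is
reported for both valences); cooling was chosen to match the discussed
cheek-cooling mechanism.

What the generator does **not** emulate: heat diffusion and physiological
dynamics within a session, glasses/hair occlusion, breathing artifacts,
illumination drift, non-rigid facial deformation, or realistic
between-participant anatomical variation (templates differ only in
brightness, texture phase and eye spacing). Passing tests therefore
demonstrate that the pipeline recovers planted effects through
registration, quantization and selection — not that real faces carry
effects of this size.

## Preprocessing

Coordinates are 0-based, row-major; rectangles are half-open.

- **Eye detection.** Otsu binarization boxes the face; within the upper
  half of the box, pixels at or above the 95th intensity percentile are
  grouped into connected components and the two with the hottest peaks are
  the eyes. Each centroid is computed on the component's hot core (60% of
  the way from threshold to peak, intensity-weighted): the raw percentile
  mask bleeds into the surrounding facial gradient and would bias a plain
  centroid by 1–2 px, enough to corrupt the inter-eye angle.
- **Registration.** Rotation = inter-eye angle difference, translation =
  eye-midpoint difference, applied with nearest-neighbour resampling so the
  output is a permutation-with-fill of input gray values. The reference is
  the participant's first baseline frame. Automatic detection replaces
  manual first-frame seeding for headless reproducibility; explicit eye
  coordinates can still be supplied.
- **Denoising.** Median filter (window 3) then Gaussian (σ = 1 px), both
  unspecified in the emulated protocol and set to the mildest standard
  values. Denoising attenuates planted deltas by ≲10% near ROI borders —
  visible in recovered trend magnitudes of ~9.1 vs. planted 10.
- **ROI model.** The geometric ratio table (centre fractions of the face
  box, sizes as fractions of D) is not published; the shipped default
  (forehead 0.40D×0.15D at 0.50 W/0.15 H; cheeks 0.20D×0.20D at
  0.25/0.75 W, 0.55 H; nose 0.15D×0.20D at centre; maxillary 0.30D×0.15D
  at 0.50 W/0.80 H) is a documented stand-in, fully user-configurable, and
  is the same table the generator uses for its ground truth.

## Features

Variances are sample variances (denominators wh−1, h−1, w−1). GLCMs
quantize 0–255 uniformly into Ng = 32 levels (unpublished; 32 is standard
Haralick practice and keeps distance-16 matrices populated in the smallest
ROIs), count ordered pixel pairs in both directions of each angle's offset
(hence symmetric matrices), and are normalized to probabilities before the
texture statistics so homogeneity and ASM stay in (0, 1]. Marginal moments
use 1-based level indices; correlation is shift-invariant, so the base
affects nothing observable. A frame whose ROI cannot populate a
co-occurrence cell (too small for the distance, or a constant patch making
correlation undefined — its marginal deviation is zero) is dropped from
the feature table with a logged warning rather than zero-filled; on
default synthetic cohorts this affects ~3% of frames (almost always the
nose at distance 16 on the diagonal angles).

## Selection

NCA uses the weighted cityblock distance D_w = Σ ω_l²|x_il − x_jl| on
z-scored features, kernel exp(−z/σ) with σ = 1 (standard practice on
standardized inputs). Kernel rows are shifted by their off-diagonal
minimum before exponentiation, so no row can underflow to zero. The
objective is maximized by gradient ascent from ω = 1 with an Armijo
backtracking line search (tol 1e-6 on relative objective change, max 500
iterations at the library level); the accepted-step trace is
non-decreasing by construction. λ is tuned on the grid
{0, 0.5, 1, 2, 4}/N by fivefold CV — stratified by class and grouped by
participant to respect the cross-subject design, falling back to plain
stratification (with a warning) when too few participants exist for group
folds — scored by mean held-out soft-LOO classification loss, ties to the
smaller λ. Reported "weights" are ω²; ranking ties break by canonical
feature-name order. A selection-frequency mode (membership counts in
per-fold top-k lists) is provided as an alternative ranking; weight rank
is the default because weights are the primary fitted quantity.

Known degenerate regime: when the training set is so small or the planted
effects so strong that soft-LOO accuracy is already 1 at ω = 1, the
gradient vanishes and all weights stay equal (selection then falls to the
name tie-break). This is inherent to the objective, not an optimizer
failure; it does not occur at the study scales used here (≥ 5 training
participants).

## Classification and evaluation

Each frame is one sample, labelled by its session (the per-group test
counts imply frame-level evaluation). z-scoring uses training-row
statistics only; zero-variance training features are dropped with a
warning before fitting. The SVM kernel scale grid {1, 2.15, 5} includes
2.15 — the value reported to work best in the emulated study, interpreted
as a MATLAB-style KernelScale (γ = 1/scale²) since the report does not
name the parameter — with costs {1, 10, 100} and fivefold CV on training
rows. Class imbalance in the Base tasks (~150 task vs. ~30 baseline
frames per participant) is mitigated by reporting F1 alongside accuracy
rather than by resampling. An optional exclusion rule drops participants
whose mean registration translation exceeds a configurable threshold,
mirroring the protocol's exclusion of one high-motion participant.

Trend analysis uses participant-level state means (frame-level tests would
inflate n) and paired t-tests, since each contrast compares two states
within the same participants; Bonferroni correction is over all 15
ROI × contrast tests.

## Problem sizes

The test suite exercises the full pipeline on a 12-participant cohort at
protocol frame counts (30/75), split into two groups so each keeps the
5:1 train:test participant ratio, with NCA fit on a deterministic
participant-and-class-stratified subsample of ≤ 150 training frames and
≤ 75 ascent iterations — the O(N²·d) pairwise tensor makes full-cohort NCA
unnecessary for weight ranking, and weights stabilize well before that cap.
`scripts/acceptance.py` uses the same sizes. Library defaults are larger
(max 500 iterations) for standalone use.

## Limitations

- The ROI ratio table and effect magnitudes are documented stand-ins, not
  published values; conclusions about real data require the study's own
  geometry and effects.
- Registration is rigid and eye-anchored; non-rigid deformation, occluded
  eyes, or eyewear defeat it.
- The pipeline is binary and cross-subject by design; within-subject or
  three-way classification is out of scope.
- Synthetic P-Base/N-Base separability is near-ceiling because planted
  effects are uniform across participants; real cross-subject variability
  is substantially larger.
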