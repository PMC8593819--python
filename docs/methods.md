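# Methods

## Overview

`somnoflow` estimates sleep-apnea severity (AHI, events/hour) and
positional-apnea status from the motion content of overnight video. The
processing chain is: frames → dense optical flow and sparse point
trajectories → respiratory-event detection (3D-CNN on flow windows, or a
random forest on respiratory-signal features) → event intervals →
AHI regression → per-position AHI via a supine/lateral track → the
positional rule and classifier. A seeded simulator generates annotated
recordings so every stage can be validated without clinical data.

All times are seconds from recording start; intervals are half-open
`[start, end)`. Flow fields store `(dx, dy)` in pixels per frame pair,
with x side-to-side and y up-and-down (row direction positive downward).

## Motion extraction

Frames are downsampled from the acquisition rate (nominally 30 Hz) to
2 Hz by frame dropping — still twice the Nyquist rate for ~0.5 Hz
breathing — and all detection operates at 2 Hz.

Two dense-flow backends satisfy one contract (mean endpoint error < 0.5 px
on rigid translations): a classical iterative Lucas–Kanade estimator
(`skimage.registration.optical_flow_ilk`, radius 7) for pixel data, and an
`exact_synthetic` oracle that returns the simulator's analytic fields,
decoupling downstream validation from flow-estimation error. Sparse
tracking initializes 768 points on a uniform grid (32×24 at 64×48),
accumulates per-pair flow sampled at the nearest pixel, and re-seeds
points that leave the frame at their grid origin so the point count stays
constant through large movements.

`total_displacement` sums L2 displacement magnitudes per non-overlapping
window — per pixel for dense flow, per tracked point for trajectories.
Signed sums are not used; opposite motions would cancel and arousals would
be invisible. Gross body movements are detected by thresholding the
1-second tracked-point series at 20,000 px, a constant defined at 640×480
and scaled linearly with pixel count (200 px at 64×48).

## Respiratory signal and baseline features

Within each 30 s window (stride 1 s) of the 768-point trajectories, the
first principal component of the centered time × coordinates matrix is the
dominant coherent motion — breathing. PC1 scores are computed from the
60×60 Gram matrix (algebraically identical to the SVD route, far cheaper
at 1,536 coordinates). Three choices the windowing leaves open:

* **Sign.** PCA sign is arbitrary; each window is flipped to correlate
  positively with its predecessor on their 58-sample overlap (first window
  arbitrary).
* **Level.** Per-window centering subtracts the window's own breathing
  mean, which would leak a spurious DC level into low-motion sections
  (apneas would retain ~40 % apparent amplitude). Consecutive windows are
  therefore offset-chained on their overlap, reconstructing the true
  displacement up to one global constant, which is removed at the end.
  When the overlap residual's spread exceeds half the window's RMS score
  the motion mode has changed (e.g. a body roll inside the window); the
  chain re-anchors at the window's own mean rather than propagate a
  corrupted level.
* **Stitching.** The signal value at second *i* comes from the window
  centered nearest *i*, evaluated at second *i*; one sample per second,
  length `T − 29` for a `T`-second record.

Per 10 s analysis window (stride 1 s) the baseline features are: the
spectral-peak frequency within 0.1–1.0 Hz (capped at Nyquist; an all-zero
window yields NaN, treated as missing, never 0 Hz), the mean of squared
displacement (movement power), and the tracked-point total displacement.
Windows are labeled `event` when at least half the window overlaps an
annotated event. NaN-rate windows are excluded from training; at
prediction they are imputed with the band floor (0.1 Hz).

## Event detection

**Windows.** A classifier window is 18 consecutive 2 Hz flow fields
(19 frames, covering 9.5 s). Training balances the skewed classes by
stride: 0.5 s inside events, 15 s outside; windows straddling an event
boundary have ambiguous labels and are discarded. "Fully inside" requires
the 9.5 s cover to end strictly before the event's end, so a 60 s event
yields exactly the starts 0, 0.5, …, 50.0 s. Test-time windows run at
0.5 s stride everywhere.

**3D-CNN.** Three conv3d(3×3×3)+ReLU+maxpool(2×2×2) blocks (8, 16, 16
channels), two dense layers (32 units, then softmax over
{normal, event}), parameterized by input resolution; inputs wider than
~32 px are first mean-pooled spatially. Training: Adam, initial learning
rate 0.001, batch 25, cross-entropy weighted event:normal = 5:1, seeded
initialization and shuffling (fixed seed ⇒ identical loss trajectory).
The implementation is plain numpy (stride-tricks convolutions, manual
backpropagation); at 64×48 one epoch over 300 windows takes ~6 s on one
CPU. Epoch counts are configurable; desk-scale studies here use 8–20
epochs, ample for the near-separable synthetic task (clinical-scale
training would use orders of magnitude more).

**Baseline forest.** 50 trees on the three features above, out-of-bag
probability estimates enabled.

**Threshold.** "Maximizing area under the curve" is not a function of a
threshold, so the operating point is chosen to maximize Youden's J
(sensitivity + specificity − 1) over candidate cutpoints — midpoints of
consecutive distinct scores, ties toward the smallest — with the published
0.1 retained as the fallback for degenerate score sets. For the forest,
thresholds are selected on out-of-bag scores; in-sample forest
probabilities are nearly 0/1 and would push the threshold to an
uninformative extreme.

**Intervals.** Thresholded positive windows cover `[t, t + 9.5 s)`;
overlapping or touching covers (merge gap 0 s by default) merge into
events, with the maximum window score as confidence. Interval
reconstruction is idempotent, and lowering the threshold never removes
positive windows.

## AHI estimation

AHI regressions absorb systematic over/under-segmentation of the detector
instead of trusting raw counts. Ordinary least squares with intercept;
predictions clipped at 0 (a negative event rate is unphysical);
rank-deficient designs are rejected naming the collinear columns. The
3-feature variant uses the detected-event count, the duration of events
longer than 9 s divided by sleep duration, and sleep duration; the
2-feature baseline uses events per hour of detected-event time (defined 0
when nothing is detected) and detected-event time as a fraction of
recording time. "Sleep duration" is total recording time; no sleep
staging is attempted.

## Position and positional apnea

The position classifier runs only where position can have changed: frame
0, then after each detected movement, on the first window whose
displacement is back under the threshold (classifying mid-movement frames
is meaningless). Labels propagate forward; equal-label neighbors merge, so
the track tiles the recording with no zero-length segments. Two backends:
a simulator-truth oracle, and a trainable stand-in (16×16 thumbnail +
logistic regression) for the pretrained pose network the interface
anticipates.

Events are attributed to the position at their start time (events spanning
a roll are rare and a start-time rule is deterministic). Per-position AHI
is count/time; a position with under 5 minutes of recording time (or none)
has an undefined AHI, and such subjects are `undetermined` — excluded from
positional training and passed through at prediction.

The rule labels a subject positional iff supine AHI ≥ 1.5 × lateral AHI
(boundary inclusive). The 3-tree forest over the six per-subject features
(per-position counts, times, AHIs) uses deterministic trees
(no bootstrap, all features per split): with 3 trees and cohort-scale
samples, bagging noise dominates the ensemble and LOOCV agreement with the
rule becomes a coin flip; deterministic trees keep its variance in check.

## Evaluation

Leave-one-person-out cross-validation refits the event classifier, the
operating threshold, and the AHI regression on each training fold; motion
extraction and per-window features are fold-independent preprocessing and
are cached per subject. Agreement is summarized by Spearman rank
correlation (average ranks for ties), Bland–Altman bias and 1.96·SD limits
(SD with n−1), and confusion metrics at the conventional AHI ≥ 15
screening cutoff. Percentages are reported to 2 decimals; undefined ratios
propagate as NaN, never silently as 0. Printed-table consistency checks
reconstruct the unique integer confusion matrix implied by a published
precision/recall pair and cohort size, then recompute accuracy and F1.

## Simulator

The simulator is the package's study population. Breathing is a sinusoid
at a subject-specific base rate drawn from 0.2–0.4 Hz with ±5 % sinusoidal
rate drift (5-minute period), ~10 % lognormal per-breath amplitude jitter,
and additive white displacement noise (SD 0.05 px). The baseline
amplitude is 1.0 px at the desk-scale 64×48 resolution — chest motion of
5–15 px at 640×480 corresponds to ~0.5–1.5 px in a 0.1× thumbnail. Events
scale the amplitude: 0.02 for apneas (residual motion, not exactly zero),
uniform(0.3, 0.7) for hypopneas (30–70 % reduction), with 1 s cosine
on/off ramps. Event counts follow `round(AHI × duration/3600)`; durations
are uniform(12, 28) s for apneas and (12, 25) s for hypopneas, separated
by ≥ 10 s of normal breathing, placed uniformly at random inside position
segments (sampled directly via Dirichlet gaps — the same conditional
distribution as rejection sampling, but fast at high densities) and kept
clear of recording edges and rolls.

Position tracks alternate supine/lateral with 2–4 rolls and a supine time
fraction drawn from 0.4–0.6. Positional subjects allocate events for a
supine/lateral rate ratio of ~6 (strongly positional patients have
near-normal nonsupine AHI; the defining threshold is only 1.5);
nonpositional subjects allocate proportionally to position time, adjusted
to stay strictly below the 1.5 ratio.

The scene is a torso-shaped elliptical blob whose pose (width, lateral
offset) encodes position, with a chest ridge translating vertically by the
breathing displacement; rendering, analytic dense flow, and analytic point
trajectories are three consistent views of the same motion model. A roll
appears as a lateral shift of the torso footprint in the flow step
crossing the segment boundary.

What the simulator does **not** emulate: photorealistic infrared
appearance, blankets and occlusion, cardiac micro-motion, camera noise
structure, breathing-waveform asymmetry, apnea-associated rate changes, or
subjects leaving the field of view. Passing synthetic studies therefore
demonstrates the correctness and internal consistency of the pipeline —
not clinical performance, which in the published setting was measured on
real infrared recordings with attached-sensor ground truth.

## Study sizes and numerical choices

Synthetic studies are sized for a single CPU: 20 subjects × 1 h for the
AHI-recovery study (AHI uniform 5–60), 12 subjects (6 positional, 6
nonpositional, AHI 20–40) for positional recovery, ~400 windows at 64×48
with two model seeds for the 3D-CNN study. Tolerances: rank correlation
≥ 0.8 and screening accuracy ≥ 85 % for AHI recovery; AUC > 0.9 for the
network; oracle equivalences are exact or at 1e−12 except the PCA-signal
correlation (> 0.99).

Degenerate inputs are handled explicitly: empty flow, single-class
training sets, all-equal scores, zero-duration positions, constant vectors
in rank correlation — each raises or flags rather than returning a silent
0.

## Known limitations

* The numpy 3D-CNN is CPU-sized; full-resolution (640×480), 25k-epoch
  training is out of scope, as are pretrained flow/pose weights.
* The 3-tree positional forest remains high-variance at 12-subject
  cohorts even with deterministic trees; across cohort draws its LOOCV
  agreement with the rule is typically ≥ 0.92 but occasionally dips to
  ~0.75. The rule itself recovers generated profiles exactly.
* Hypopnea simulation reduces amplitude only; no desaturation or arousal
  surrogate exists, so apnea/hypopnea subtypes are not distinguished
  (detection is a single event class, as in the binary task).
* The respiratory signal's offset chaining assumes breathing is the
  dominant mode outside gross movements; mixed modes (e.g. persistent limb
  motion) would degrade the reconstructed level.
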