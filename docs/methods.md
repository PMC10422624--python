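# Methods

## The synchrony model

`posesync` quantifies how synchronized the body movements of several
people are, frame by frame, from 2-D keypoint streams in the
18-keypoint skeleton convention of bottom-up pose estimators (nose,
neck, eyes, ears, shoulders, elbows, wrists, hips, knees, ankles).  A
*body part* is the planar vector between two adjacent keypoints; 17
parts cover the shoulder sections, arms, trunk bodylines, legs and the
head/face chain.  For one part and one unordered person pair the
synchrony score is a function of the angle θ between the two part
vectors:

* **perpendicular** mapping: s(θ) = |1 − θ/90°|.  A 90° angle means a
  complete absence of synchronization; both 0° and 180° score 1, so
  anti-phase movement counts as synchrony.  s(θ) = s(180° − θ).
* **linear** mapping: s(θ) = 1 − θ/180°, strictly decreasing, with 180°
  as complete absence.
* a smooth **cosine** alternative (|cos θ|, same endpoints as
  perpendicular) sits behind the same switch for users who prefer a
  differentiable map.

The piecewise-linear maps were chosen as defaults over |cos θ| because
the constraint is only on the endpoint semantics and linear maps give
exact analytic values for tests and interpretation.

Angles are computed as `atan2(|u×v|, u·v)`, which is algebraically the
arccos of the normalized dot product but exact for parallel,
antiparallel and orthogonal operands.  Zero-length part vectors have no
direction and are treated as missing, not scored 0.

The comparison can be **same-side** (right arm vs right arm) or
**opposite-side**: A's part against B's mirror part reflected about the
vertical image axis (x negated), so two people facing the camera making
mirror-image gestures score exactly 1.  The reflection rule is the
package's own choice of how "mirroring counts as synchronization"
should behave; it is the unique linear rule that makes a true mirror
pair maximal.

A frame's per-part score for N persons is the unweighted arithmetic
mean over all unordered pairs with a defined score (per-pair records
are also available for audit).  Per-second series average the frame
scores within each integer-second bin, ignoring missing frames;
seconds with no defined frames emit missing rows so row counts are
preserved for alignment.  All scores are invariant to translation,
uniform scaling, and global rotation applied to everyone, and to
person order.

## Distance and the entanglement record

Inter-person distance is measured between hip centers (midpoint of
l_hip/r_hip — the most stable reference point) and normalized by
H = h_A + h_B, the sum of the two persons' *pose-independent body
heights*:

    h = |neck→hip_center| + mean over sides (|hip→knee| + |knee→ankle|)
        + |neck→nose|

Each term is a segment length, so h does not change when limbs
articulate.  Dividing by H makes d dimensionless and invariant to
camera zoom; a `multiply` compatibility mode scales by H instead, for
parity with conventions that phrase the normalization as a
multiplication, but has pixel² units and is not zoom-invariant.  The
entanglement record E = {S, d} bundles a pair's 17-score synchrony
vector with this distance.

## Emotion stream and dataset assembly

The facial-expression stage (external to this package) yields one
probability per second for each of seven emotions (angry, sad,
disgusted, neutral, happy, surprised, fearful), averaged over detected
faces; the probabilities are used as-is and not renormalized.  The
dominant collective emotion is the argmax, with exact ties broken
alphabetically (ties do not occur in practice; the rule exists so the
label is a total function).  The joined dataset inner-joins per-second
synchrony features with labels on the second index; rows with any
missing synchrony slot are dropped rather than imputed, mirroring the
practice of removing occluded data points.

## Synthetic data generator

Real multi-person rehearsal footage cannot be shipped, so every stage
is exercised on synthetic streams.  Each person is a rigid-segment
skeleton with fixed canonical proportions (torso 50 px, hips ±10,
shoulders ±18, upper/lower arm 30/25, upper/lower leg 40/40, neck→nose
20, giving the closed-form body height 150 px).  Eleven joint angles
(trunk, shoulder line, head, per-side arm/elbow and leg/knee) follow

    angle(t) = base + amplitude · [ρ·shared(t) + (1−ρ)·private(t)] + ε

with smooth sinusoidal programs (0.1–0.5 Hz, random phase), a group
shared program, per-person private programs, and per-frame Gaussian
jitter (default SD 3°).  ρ ∈ [0,1] is the synchrony level: at ρ = 1
with no jitter everyone performs the identical gesture and all
same-side scores are exactly 1; mean synchrony is non-decreasing in ρ.
Streams default to 5 fps, matching the throughput of CPU pose
estimation on video.  Keypoints drop out with a configurable
probability (scalar or per-keypoint) by setting detector confidence
to 0.

The emotion generator draws, per second, a baseline label from a
configurable happy/sad/angry distribution (default 54/42/4%, the
imbalance typical of this kind of rehearsal data), assigns it a high
softmax score, and adds coupling terms linear in *standardized* group
synchrony (z-scores of the overall, arm-group and leg-group means over
the session): happy rises with body synchrony, sadness/disgust fall
with leg synchrony, anger/surprise fall with arm synchrony.  Disgust
and surprise share their driver and coefficient with sadness and anger
but rest a full unit lower, so their probabilities rise when synchrony
falls (the negative synchrony–disgust/surprise association) while the
dominant label stays in {happy, sad, angry}.  Standardization is what
makes the coupling express "more/less synchronized than the session
norm"; coupling raw score levels would saturate, since their absolute
level depends on the metric variant.  At coupling 0 the dominant labels
follow the baseline distribution exactly.

What the generator does *not* emulate: detector noise correlated with
pose (occlusion is independent dropout here), camera motion,
perspective foreshortening, person tracking errors, or any musical
structure in the motion.  Passing tests therefore demonstrate the
correctness and statistical behavior of the pipeline, not field
accuracy on real footage.

## Statistical chain

* **Min–max scaling** to [0,1] per feature, with stored bounds for the
  exact inverse; constant features are an error by name.
* **Cubic-spline resampling** (optional, off by default) uses
  not-a-knot end conditions: C² everywhere and exact on cubic
  polynomials.  (Natural end conditions were rejected because forcing
  zero second derivatives at the ends breaks cubic reproduction.)
  At least 4 support points; no extrapolation.
* **SMOTE** oversamples every minority class to the majority count;
  each synthetic point is a + λ(b − a), λ ~ U(0,1), between a minority
  sample and one of its k = 5 nearest same-class neighbors (k capped
  at class size − 1).  Implemented directly in the package (the
  algorithm is a dozen lines over a k-NN query); deterministic under
  seed, originals preserved verbatim.
* **Stratified K-fold** (K = 3) keeps per-fold class proportions
  within one sample of global.  By default SMOTE is applied to the
  training fold only, so synthetic points never leak into the test
  fold; a `paper_mode` switch balances the full dataset before
  splitting for comparison with pipelines that did so.
* **Pearson correlation** between each synchrony column and each
  emotion-probability column, pairwise-complete, two-sided p from the
  t transform with n − 2 df.  Undefined pairs (constant column, < 3
  rows) are flagged, not silently NaN-propagated.  Raw p-values are
  the decision quantity; a Bonferroni-scaled copy is written alongside
  for reference.
* **Forward stepwise OLS** (dependent variable: an emotion channel,
  default disgust): at each step the candidate maximizing adjusted R²
  enters if its partial-F p-value — Bonferroni-corrected by the number
  of candidates examined at that step, since the entrant is the best
  of them — is below p_enter = 0.05, and the adjusted-R² gain is
  ≥ 1e-4; both thresholds are configurable because only the criterion
  family is fixed.  The correction keeps the chance of admitting any
  predictor into an all-noise model at about p_enter regardless of how
  many candidates compete (a raw per-candidate threshold would admit
  noise with probability 1 − 0.95^k).  The final refit reports B, SE,
  standardized beta = B·sd(x)/sd(y), t and two-sided p in selection
  order.  Exactly collinear candidates are skipped with a warning.

Correlations use pairwise-complete deletion while the regression is
listwise — the two analyses legitimately see different row counts.

## The 1-D CNN classifier

The classifier maps the 17 synchrony scores, treated as a length-17
single-channel sequence in canonical part order, to one of three
emotion labels.  Architecture: conv(32 filters, kernel 3, ReLU) →
maxpool 2 → conv(64, 3, ReLU) → maxpool 2 → conv(64, 3, ReLU) →
flatten → dense 64 → dense 32 → dense n_classes with softmax.  All
convolutions are same-padded: the length trace is 17 → 8 → 4 with
flatten 256, and with valid padding a third kernel-3 convolution would
be infeasible (17→15→7→5→2), so same-padding is forced by the stated
stack.  Parameter count: 37,315 (asserted in tests to guard drift).
Training: categorical cross-entropy, Adam at learning rate 1e-4, batch
100, fixed 20 epochs, no early stopping.  Weights initialize from the
standard uniform fan-in scheme under an explicit seed; biases start at
zero.  Forward, backward and Adam are implemented in numpy; runs are
deterministic for a fixed seed up to BLAS threading.

Because the step budget is fixed by the epoch count, batch size and
learning rate, convergence is governed by dataset size.  The end-to-end
label-recovery benchmark uses 3 persons, 30,000 seconds at 5 fps,
ρ = 0.5, jitter 3°, coupling 24 — sized so the fixed 20-epoch schedule
reaches its plateau (~0.93 test accuracy against a ~0.94 linear-probe
ceiling set by the generator's label noise near class boundaries).  The
label-shuffle control, which only needs to demonstrate chance-level
performance, trains on a 3,000-row subsample.

## Numerical and degenerate-input choices

* Detector confidences below c_min = 0.1 mark a keypoint absent; its
  stored coordinates are retained (round-trips are exact) but carry no
  meaning.
* Inputs in the 17-keypoint convention (no neck) get a synthetic neck
  at the shoulder midpoint, flagged `synthetic` and never written back.
* Fewer than two poses in a frame yields all-missing scores, not an
  error; an empty overlap in the dataset join is an error.
* Person identity is taken from input ids; for anonymous streams a
  greedy nearest-hip-center matcher is available.  Synchrony itself is
  computed over all unordered pairs per frame and does not require
  identity.
* Labels too rare to stratify (fewer than K rows) are dropped before
  the train/test split, with a log message.

## Known limitations

2-D projected angles conflate out-of-plane motion with asynchrony; no
lag-tolerant synchrony (cross-correlation or coherence) is computed;
the regression treats seconds as independent although the series is
autocorrelated (inference is optimistic); the CNN architecture is
fixed rather than tuned.  These mirror the scope of the measurement
procedure the package implements.
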