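# Methods

## Problem and model

Manual lifting is a principal risk factor for occupational low-back injury.
The revised NIOSH lifting equation scores a lifting task by

    RWL = LC · HM · VM · DM · AM · FM · CM,        LC = 23 kg

where the multipliers penalize the horizontal hand location H (HM = 25/H,
H in cm), the vertical hand location V (VM = 1 − 0.003|V − 75|), the
vertical travel D (DM = 0.82 + 4.5/D, with a 25 cm minimum travel), the
asymmetry angle A (AM = 1 − 0.0032·A, zero above 135°), the lifting
frequency F (FM, from the published frequency × work-duration table with a
V < 75 cm split at high frequencies), and the hand-object coupling (CM:
good 1.00; fair 0.95 below 75 cm else 1.00; poor 0.90).  The Lifting Index
LI = load / RWL flags increased risk when it exceeds 1.0.

One deliberate deviation from the applications-manual tables: the default
horizontal multiplier keeps the 25/H decay at any reach instead of zeroing
beyond 63 cm.  Consumer-grade skeleton estimates routinely place the hands
beyond 63 cm on tasks that are clearly scoreable, and a hard zero there
turns a small estimation error into a categorical change of the RWL.  The
standard cutoff is available via `horizontal_multiplier(h, max_h_cm=63)`.
Negative measured V (possible with sensor noise) is clamped to the floor
only inside the vertical multiplier; the raw value is preserved upstream so
that error models see the uncensored geometry.

This package estimates H, V, D, A, and F automatically from 3D skeleton
joint time series (20 named joints per frame, meters, Z-up world frame,
floor at Z = 0, ≈30 Hz), and corrects the systematic errors of depth-camera
skeletons by regression against a reference stream.  Coupling and work
duration remain user inputs (defaults: fair, ≤1 h).

## Geometry

The hand anchor is the midpoint of the two *wrist* joints (configurable to
the hand tips); skeleton algorithms track wrists more stably.  Per frame:

- H = 100 × the horizontal (XY) distance from the ankle midpoint to the
  hand midpoint's floor projection;
- V = 100 × the hand midpoint's Z;
- A = the unsigned floor-plane angle between the asymmetry line (ankle
  midpoint → hand projection) and the mid-sagittal direction, in [0°, 180°].
  When the hands project onto the ankle midpoint the angle is undefined and
  reported as 0 with a flag;
- D = |V(destination) − V(origin)| across a lift cycle.

The mid-sagittal direction comes from a body-centric frame: origin at the
mean of the four shoulder/hip joint centers; Z the world vertical; X the
horizontal component of the hip-plane normal (cross(right_hip − hip_center,
left_hip − hip_center)), unit-normalized; Y = Z × X.  The hip-plane normal
fixes X only up to sign, so the anterior sign is chosen by temporal
continuity with the previous frame, seeded on the first frame by requiring
the mean wrist position to have non-negative body X (people rarely hold
both hands behind their back at the start of a recording).  Degenerate hip
triangles (area ≤ 1e-9 m²) and vertical hip-plane normals raise errors.

## Signal preprocessing

Fixed pipeline for paired streams, applied in this order:

1. 4th-order low-pass Butterworth at 7 Hz on every coordinate channel of
   both streams.  "Recursive" is read as a causal single pass (initialized
   at the first sample to suppress the startup transient); a `zero_phase`
   switch enables forward–backward filtering for users who prefer no lag.
2. Savitzky–Golay smoothing (degree 3, window 33 ≈ 1.1 s) on the noisy
   stream only.
3. Linear-interpolation resampling of both streams to a uniform 30 Hz grid.
4. Temporal alignment by the lag maximizing the normalized cross-
   correlation of the mean-removed right-wrist Z series.  The per-lag
   normalization (dot product over the product of segment norms) avoids the
   small-lag bias of raw cross-correlation; the search is bounded to ±3 s
   because simultaneous recordings begin within a synchronization gesture
   of each other, and an unbounded search on near-periodic motion could
   snap to a whole-period offset.
5. Outlier screening: an aligned pair is rejected when the largest
   per-joint distance between the two skeletons exceeds 0.30 m — an
   automated, reproducible surrogate for manual inspection of gross
   skeleton-fitting failures.  The threshold is configurable.

Because step 2 is one-sided, an uncorrupted pair still shows sub-cm/
sub-degree parameter deltas on fast motions (smoothing attenuation); this
is a property of the published pipeline, not of the corruption model, and
it sets the noise floor visible in the zero-noise generator tests.

## Lift-cycle detection

Lift cycles run from an origin (local minimum of the mean hand height) to a
destination (the next local maximum).  The hand-height signal is band-passed
to natural human lifting frequencies (default 0.05–1.0 Hz, i.e. 3–60
lifts/min; the band is configuration).  Candidate destinations are maxima of
the band-passed signal (prominence gate at 0.25 σ); each is snapped to the
nearest maximum of a lightly smoothed copy of the unfiltered signal within
a quarter-period window (the dominant period is estimated from the
band-passed signal's zero crossings); the origin of each cycle is the
lowest smoothed hand height since the previous destination.  Cycles with
hand-height excursion under 5 cm are discarded (micro-cycle gate).
Frequency is 60 × n_cycles / recording duration.  Per trial, H and A are
evaluated at each cycle's origin frame (the beginning of the lift), V at
origin and destination, D from the pair, and each parameter is averaged
over cycles.

## Error-correction model

For each parameter x ∈ {H, V, A} the error δx = x(reference) − x(noisy) is
modeled as a function of the noisy skeleton's pose, represented as the 60
body-frame joint coordinates (20 joints × 3).  Body-frame features make the
model invariant to where in the room and in which direction the subject
stands.  D is not modeled directly: it is derived from corrected V at the
cycle origin and destination.

Training data are mirror-augmented: every sample is duplicated with the
body-frame Y axis negated and left/right joint labels swapped (H, V, and
the unsigned A are mirror-invariant, so the targets carry over).  The
augmentation compensates for left/right asymmetries in data collection and
is applied to training data only, never to assessment input.

The regressor is scikit-learn's `GradientBoostingRegressor` with Huber loss
(transition quantile 0.9), 150 trees, learning rate 0.05, depth 3, subsample
0.8, and `max_features = 0.3`.  Training sets larger than 15,000 samples
are subsampled (seeded) to that cap: the error fields being learned are
smooth low-order functions of pose, which ~10⁴ samples resolve, and the cap
keeps a full leave-one-subject-out sweep (subjects × parameters fits) to a
few minutes on one core.  All fits are deterministic given the seed.

Validation is leave-one-subject-out (LOSO): for each subject, ensembles are
trained on all other subjects' samples and evaluated on the held-out
subject's non-mirrored samples, reporting bias (mean error), variance, and
MAE for raw (δx) and modeled (δx − prediction) errors.  Held-out
predictions never touch held-out labels; the test suite includes a canary
that corrupts held-out labels and asserts identical predictions.

Models persist as a joblib payload plus a JSON metadata sidecar (feature
schema version, subjects, seed, hyperparameters); loading refuses a schema
mismatch.

## Synthetic paired data

The generator emulates a laboratory session: six subjects, four trial kinds
each (lifting, walking, arm movement, smooth random motion), 30 s at 30 Hz
by default (≈21,600 frames, the scale of a small paired-capture corpus).
A kinematically simple articulated chain with fixed segment lengths
(scaled by a per-subject anthropometric factor drawn in 1.0 ± 0.1) is posed
so the wrist midpoint follows a prescribed (H, azimuth, V(t)) trajectory;
the torso leans and the pelvis crouches as the hands go low, and the feet
stay planted with the ankle midpoint at the origin.  Lift trials drive V
with a raised-cosine between the programmed origin and destination heights
at the programmed frequency, starting at the origin, so at every cycle
origin the geometric H, V, A equal the programmed values exactly (to
machine precision before corruption).  Distractor motions are mildly
aperiodic (incommensurate sinusoid pairs, seeded smooth noise) — both for
realism and so that alignment by cross-correlation is well posed.  The
generator refuses anatomically impossible requests (H beyond scaled arm
reach, |A| > 85°, out-of-range hand heights).

The corruption model produces the noisy stream from the reference stream:

1. systematic underestimation: the hand/wrist joints' horizontal offset
   from the ankle midpoint and their height are shrunk by `bias_sign`
   (default 10%), reproducing the observation that depth-camera skeletons
   underestimate the lifting parameters (so δH, δV > 0 on average);
2. a smooth pose-dependent bias field: each joint is displaced by a linear
   function of the body-frame hand-midpoint position (amplitude 3 cm).
   Dataset-level coefficients are shared across subjects, with a 0.25-scaled
   subject-specific perturbation — the shared part is what a LOSO model can
   learn, the subject part is irreducible inter-individual variation;
3. white Gaussian joint noise (σ = 1 cm);
4. sparse gross outliers (rate 1%, one joint displaced by 0.8 m).

What the generator does *not* emulate: occlusion by scene objects, depth-
dependent noise, skeleton-fitting failure modes with temporal structure,
soft-tissue artifacts, or realistic joint-angle limits.  Passing tests
therefore demonstrate that the pipeline and learning machinery recover
known structure under a plausible error model — not field accuracy on any
particular camera.

## Numerical choices and degenerate inputs

- FM table lookups round a frequency to the nearest tabulated row;
  frequencies above 15 lifts/min give FM = 0.
- RWL = 0 with a positive load reports LI = +inf and an unbounded-risk flag.
- Resampling requires ≥ 2 frames; alignment requires ≥ 2 s overlap and
  non-constant right-wrist height.
- A constant hand-height signal yields zero cycles (an empty list from
  detection, an explicit error with diagnostics from trial summarization).
- Problem sizes in the test suite: the LOSO acceptance check uses the
  six-subject ~21.6k-frame corpus above; filter/alignment/cycle checks use
  30–60 s single trials; unit tests use hand-built 20-joint poses.

## Known limitations

- The articulated chain is not biofidelic (no joint-limit or balance
  constraints); it exercises the geometry and learning, not biomechanics.
- Coupling and work-duration classes are user inputs; no attempt is made to
  infer grip quality or shift structure from the recording.
- The cycle detector assumes a dominant lifting rhythm within the
  configured band; interleaved tasks (carrying, lowering-only) are out of
  scope.
- Error models transfer across subjects only to the extent the error field
  is shared; subject-specific bias components remain uncorrected, which is
  exactly what the LOSO protocol measures.
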