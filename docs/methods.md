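# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `motionkit` pipeline, in the order data flows through
it.

## Skeleton model and preprocessing

A recording is a sequence of 25 named 3D joints (meters) at a nominal
30 Hz with timestamp jitter. Joints missing in a frame are NaN; signals
that need a joint drop those frames, and a recording with more than 10% of
its frames unusable for a signal is rejected outright rather than
interpolated across.

Scalar signals derived per frame (joint angles, CoM components) are
computed on the raw jittered timestamps, then resampled onto a uniform
100 Hz grid through a cubic-spline interpolant and low-pass filtered with
a second-order Butterworth filter, 10 Hz cutoff. The filter is applied
forward–backward (`filtfilt`), so it is zero-phase — cycle timing is not
lagged — at the cost of squaring the magnitude response (the single-pass
gain at the cutoff is 1/√2; the effective two-pass gain is 1/2).
Resampling before filtering matters: the Butterworth design assumes
uniform sampling.

Two simultaneous recordings of the same motion are aligned by the lag
maximizing their cross-correlation (mean-removed, ties toward the smallest
absolute lag). Integer-sample shifts are recovered exactly; sub-sample
alignment is out of scope.

## Geometry

* **Segment angles** are `arccos` of the inner product of unit vectors
  along the two segments, in [0°, 180°]. The knee angle uses
  hip–knee–ankle; the trunk angle is the spine segment (pelvis → upper
  spine) against the vertical.
* **Vertical** comes from the floor: a RANSAC plane fit (3-point
  hypotheses, 1 cm inlier threshold, 500 iterations, SVD refinement on
  inliers, seeded RNG) with the subject's upside and foot positions as
  priors — a plane farther than 10 cm from a foot is rejected. When no
  point cloud is available the camera is assumed level and the configured
  up direction is used.
* **Anatomical frame**: the frontal (lateral) plane is spanned by the
  shoulder line and the spine; the sagittal plane is perpendicular to it
  and contains the spine; AP and ML are the intersections of those planes
  with the transverse plane. Implementation: vertical = floor normal, ML =
  shoulder line orthogonalized against it (subject-left positive), AP =
  ML × vertical (anterior positive). Using the floor normal — not the
  spine — as the vertical keeps trunk lean measurable; a spine-based
  vertical would absorb the very bending angle being measured. For sway
  analysis the frame is frozen from the median pose of the first phase;
  recomputing it per frame would leak trunk motion into the axes.
* **Head bending** projects the head segment (upper spine → head) and the
  spine segment into the sagittal and frontal planes and takes the signed
  angle difference in each plane: forward (ventral) positive, subject-left
  positive. The reported posture features follow the clinical sign
  convention instead — forward bending *negative* — so the extraction
  pipeline negates the sagittal components (trunk and forward-head); the
  lateral head bend is reported as an absolute value.
* **CoM**: weighted average of the midpoints of six segments
  (head–upper-spine, both shoulder–wrist arms, upper–lower spine, both
  hip–ankle legs). Default weights (0.36, 0.05, 0.05, 0.22, 0.16, 0.16)
  come from standard anthropometric segment-mass tables and are
  configurable. A literal "average of wᵢCᵢ over N" with mass-fraction
  weights is not scale-correct, so weights are renormalized to sum to 1;
  the literal 1/N mode remains selectable (`SegmentWeights(normalize=False)`)
  for comparison. Only the transverse-plane AP/ML projections, centered
  and in cm, enter the sway analysis; they are passed through the same
  resample+filter chain as the angle signals.

## Movement cycles

Cycles are minimum–maximum–minimum sequences of an angle signal. Maxima
require a prominence of at least 1° (3° for the trunk signal in the
sit-to-stand task, where secondary instability peaks are ~6° and smaller
wiggles are tracker noise, not hesitations). Boundary minima for each peak
are chosen from the local minima (and signal endpoints) between adjacent
peaks by minimizing `value + (2·prominence)·|Δt|`: depth dominates, but
among the near-equal noise dips of a flat baseline the one nearest the
peak wins, so idle time before and after a movement does not stretch the
cycle. Endpoints qualify as boundaries only when the signal has descended
at least one prominence below the peak there — a trailing rise without a
closing descent forms no cycle. Cycles shorter than 0.1 s are discarded as
noise. Per cycle the amplitude is the peak-to-peak excursion, the duration
the boundary-to-boundary time, and the peak speed the maximum absolute
spline-derivative of the angle within the cycle.

Known limitation: in a flat noisy baseline the nearest noise dip to a
movement's foot sits at the dip spacing of the noise (~0.1–0.3 s), so the
first and last cycle of a trial carry a duration bias of that order. This
creates a floor on the extracted duration dispersion (TDv) that is large
relative to its between-severity differences — consistent with duration
variability being the weakest discriminator in practice.

## Task features

* **Leg agility**: `MKAm`/`TDm` are means of per-cycle amplitudes and
  durations; `MKAv`/`TDv` their coefficients of variation (std/mean —
  dimensionless, which is what makes the printed values unit-free);
  `SPm` the mean of per-cycle speed maxima (of |velocity|); `PM` the count
  of poor movements, cycles whose amplitude *and* duration both fall below
  25% of the trial means. Poor cycles are included in the means by default
  (a config switch excludes them and recomputes once).
* **Arising from chair**: `NPeaks` is the number of detected trunk-bending
  cycles, `MBA` the largest cycle amplitude, `TD` that cycle's duration,
  and `SPm` the mean absolute trunk angular velocity within it.
* **Posture**: two quasi-static phases (10 s each; the boundary defaults
  to the midpoint of the recording). `FTB`/`FHB`/`LHB` are Phase-1 means
  of the trunk, forward-head and (absolute) lateral-head bending angles;
  the variation terms are absolute differences of the phase means —
  magnitudes, since the monotone severity display needs a worsening
  direction, not a sign.
* **Sway**: per-axis range (max − min), total path length (Σ|Δ|), mean
  velocity (path/duration), and the convex-hull area of the (AP, ML)
  cloud (0 for degenerate hulls). Computed over the full task by default,
  with per-phase values and Phase2 − Phase1 deltas available from the
  audit signals.

## Selection and scaling

Parameters are normalized by the healthy-control group mean, so 1 is the
healthy reference; counts with a natural zero (`PM`) pass through
unnormalized. The elastic net (L1/L2 mix 0.5, penalty by 10-fold CV with
the one-standard-error rule, features standardized, seeded folds) screens
the set; the mix keeps groups of correlated parameters together rather
than arbitrarily picking one. Because ordinal scores are not ratio data,
retention is confirmed by Spearman rank correlation (tie-corrected;
t-approximation for n > 8, exact permutation below) with the compound keep
rule |ρ| > 0.3 and p < 0.05, and each parameter's PD-vs-HC discrimination
is validated by a two-sided Mann–Whitney U test (normal approximation with
tie correction, Z signed by the PD shift direction).

For classifier input each parameter is mapped monotonically to [0, 1]:
severity-increasing parameters as `(p − 1)/(p_max − 1)`, severity-
decreasing ones reciprocal-reversed first; `PM` is min–max scaled from 0.
Worsening directions come from the Spearman sign; observed training
extrema are stored so new instances clip instead of extrapolating. Scores
are min–max scaled to [0, 1] as well.

## Classifiers and protocols

* **kNN**: Euclidean metric, default k = 3; vote ties decrement k until
  broken; distance ties at the k-th neighbor resolve by stable index
  order.
* **Ordinal regression**: cumulative-probit model (no intercept;
  thresholds absorb it). Constant feature columns are dropped per fit;
  perfect separation leaves the fit flagged but prediction defined.
* **SVM**: polynomial kernel `(γ u·v + r)^d`, one binary machine per class
  pair sharing one (C, γ, r, d), majority vote, ties broken by summed
  decision values. A grid search (C ∈ {0.1, 1, 10, 100}, γ ∈ {0.1, 1, 10},
  r ∈ {0, 1}, d ∈ {1, 2, 3}) by inner stratified CV is available, ties
  toward smaller C then smaller d; the cohort-level defaults fix d = 2
  (the best-performing degree), C = 10, γ = 1, r = 1 — a 72-point grid
  inside leave-one-out on 26 subjects adds variance, not information.
* **Protocols**: deterministic leave-one-out, and stratified 10-fold
  repeated (default 100 seeded shuffles) with accuracies averaged over
  repeats. Reports carry overall accuracy, per-class accuracy (unweighted
  mean of class recalls — the right summary under class imbalance), and
  for ordinal labels the absolute class error distribution `e_c = |C − C′|`
  with its maximum.

Severity-class labels use ordinal codes (0 = HC, 1–3 = increasing PD
severity). For the sway task, whose score is a subscale sum rather than a
class, 3-class labels are balanced rank tertiles of the sum.

## Reliability

The inter-rater ICC is the single-measure two-way random-effects
absolute-agreement form, computed from the two-way ANOVA mean squares,
with the F-based 95% CI (Satterthwaite approximation for the denominator
degrees of freedom). Single-measure (not average-measure) because each
rater scores a subject once. Interpretation bands: < 0.5 poor, 0.5–0.75
moderate, 0.75–0.9 good, > 0.9 excellent; boundaries go to the higher
band. Negative ICCs are returned as computed; a grid with no
between-subject variance returns 0 with a warning. Tracking accuracy
between two measurement systems is the Pearson correlation of paired
parameter sample sequences concatenated across trials in acquisition
order.

## Synthetic motion generator

The generator emulates the statistical structure the pipeline assumes,
not musculoskeletal physics:

* **Leg agility** — the ankle swings about a fixed knee so the knee angle
  follows a contiguous train of raised-cosine cycles; per-cycle amplitudes
  and durations are Gaussian around profile means with profile CVs. Poor
  movements are injected as cycles at 15%/16% of the trial-mean amplitude/
  duration (duration floored at 0.12 s — shorter bumps are unresolvable
  through the 10 Hz analysis band).
* **Sit-to-stand** — the upper body rotates rigidly about the pelvis in
  the sagittal plane through one main raised-cosine bend (profile `MBA`,
  `TD`) plus Bernoulli secondary 6° peaks emulating instability events.
* **Posture/sway** — two 10 s phases with constant trunk/head bending
  targets (Phase 2 shifted by the profile deltas) and a whole-body AP/ML
  sway translation: a stationary AR(1) (Ornstein–Uhlenbeck, τ = 1 s)
  low-passed at 2 Hz and scaled to the profile's stationary SD in cm, with
  a Phase-2 scale multiplier.
* **Sampling** — 30 Hz with 3 ms timestamp jitter; additive joint noise of
  2 mm SD, temporally correlated (AR(1), ~0.3 s) and band-limited at 2 Hz.
  The band limit is deliberate: path-length features integrate velocity,
  and a spectrally white (or raw-AR) noise of any realistic amplitude
  would dominate the sway path length by an order of magnitude — real
  depth-camera skeletons are SDK-smoothed and do not show that behavior.

Severity profiles (HC, then three worsening classes) are fixtures, not
clinical claims: every parameter moves monotonically in its worsening
direction across classes (validated at cohort construction), with
magnitudes qualitatively consistent with published healthy-vs-patient
gaps. One deliberate deviation: leg-agility cycle durations are scaled up
(0.50 → 0.92 s across classes) relative to the fastest published medians,
because a 25%-of-mean poor-movement duration below ~0.1 s cannot survive
the pipeline's own 10 Hz low-pass; the worsening direction is preserved.
The default class separations are calibrated so that the intended
default-cohort properties hold (severity-monotone nested class means; a
d = 2 SVM reaching ≥ 90% HC-vs-PD leave-one-out accuracy with 3-class
errors never exceeding one class in ≥ 95% of seeded cohorts).

Cohorts default to 12 HC + 14 PD (5/5/4 across classes), with subject-
level lognormal variability (σ = 0.06) on profile magnitudes, one trial
per task per subject, and a simulated postural-instability subscale sum
(≈ 4 × class with integer noise) as the sway-task score. Everything is
reproducible from a single seed.

What passing tests on synthetic data do **not** show: robustness to
occlusions and tracking dropouts, to non-stationary tremor superimposed on
voluntary movement, to camera miscalibration, or to the skeleton-model
biases of a particular SDK. The generator's noise is stationary and
Gaussian; real artifacts are neither.

## Numerical choices

* Angle computations clip cosines to [−1, 1]; degenerate geometry
  (zero-length segments, coincident shoulders) raises typed errors rather
  than returning NaN.
* Re-filtering an already-filtered signal is *not* identical to filtering
  once except at DC: the in-band attenuation (|H|² per zero-phase pass,
  0.9984 at 2 Hz) compounds. Tests assert the analytic bound.
* Elastic-net folds, RANSAC sampling, 10-fold shuffles and all generator
  draws take explicit seeds; leave-one-out is seed-free and deterministic.
* ICC with perfect agreement returns a degenerate CI of [1, 1]; the
  F-based CI is otherwise computed even for negative point estimates.
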