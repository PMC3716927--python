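# Methods

This note documents the models implemented in `arthroguide`, the
parameter choices that matter, the numerical details, and the limits of
what the synthetic components can show.

## Coordinate conventions and units

All frames are right-handed. Positions are in cm, time in seconds,
angles in radians, pixels for image quantities. Quaternions are stored
w-first and kept on the unit sphere (renormalized on ingestion when off
by more than 1e-6, with a warning). Forces are device-normalized
(stiffness × cm); no Newton calibration is attempted because none is
available for the target hardware class.

## Stereo marker tracking

A square marker of side `s` (default 4 cm) defines the marker frame;
its canonical corners sit at (±s/2, ±s/2, 0), counter-clockwise
starting top-left. Pose recovery from one camera solves the planar
homography `H` between the canonical square and the four observed
corner pixels by the direct linear transform with Hartley
normalization, decomposes `K⁻¹H` into two rotation columns and a
translation with the scale `λ = 2/(‖h₁‖+‖h₂‖)`, completes the rotation
by the cross product, and re-orthonormalizes by SVD
(`R = U·diag(1,1,det(UVᵀ))·Vᵀ`). The sign of `λ` is chosen so the
marker lies in front of the camera. With four exact correspondences the
homography is exact and recovery is accurate to machine precision;
with pixel noise the translation error grows with depth, which the test
suite checks by Monte-Carlo.

The resolution cascade per frame: left camera if it detected the
marker, else right camera with the pose chained into the left frame
through the fixed `T_rl` (obtained from the rig configuration; how it
is calibrated is outside this package's scope), else the previous
sample held verbatim with an updated timestamp and `source=held`. Held
samples keep equal weight in downstream fitting; the weights argument
of `fit_curve` allows down-weighting them if desired.

One notational caution: `T_ml` and `T_mr` here map *camera* coordinates
into the *marker* frame, so `T_rl = T_mr⁻¹ ∘ T_ml` maps left-camera
points to right-camera points; the extrinsic returned by
`estimate_pose_from_square` is the opposite direction (marker → camera),
which is what a tracked sample stores.

## NURBS trajectory model

The basis is the Cox–de Boor recursion with 0/0 terms taken as zero, on
a clamped (non-periodic) knot vector with end knots repeated `p+1`
times; the parameter domain is closed at `u = 1` (the final knot
activates the last non-empty span). The rational basis divides by the
weighted sum, so partition of unity holds by construction; the
implementation keeps it below 1e-12 on a dense grid, and curve
evaluation agrees with an independent evaluator (a B-spline in
homogeneous 4-D coordinates followed by perspective division) to 1e-10.

**Fitting.** Sample times give chord parameters
`ūᵢ = (tᵢ−t₀)/(t₁−t₀)`. Interior knots are placed by the standard
parameter-averaging rule for least-squares approximation (with
`d = n/(m−p)`, knot `u_{p+j}` interpolates between `ū_{⌊jd⌋−1}` and
`ū_{⌊jd⌋}`), which guarantees every basis function is supported on data
and keeps the collocation matrix full rank. The first and last control
points are pinned to the first and last data points (eliminated by
substitution); the `m−2` interior control points solve the linear least
squares `min Σᵢ‖C(ūᵢ)−Qᵢ‖²` per coordinate against the shared basis
matrix, via `numpy.linalg.lstsq` with a rank check. Weights are fixed
inputs defaulting to 1 and are never optimized. Orientation quaternions
are not spline-fit; the curve represents positions only.

Default degree is cubic (`p = 3`), the standard choice for smooth
trajectory representation; `m = 15` control points for a 450-sample,
15 s recording gives ~30× compression while keeping the RMS distance to
the noise-free ground truth well under the tracker noise SD.

**Closest-point projection** minimizes the squared distance over a
coarse scan of 512 parameters (ties break toward the smaller
parameter) followed by Newton iteration on
`g(u) = ‖C(u)−x‖²` using analytic first and second curve derivatives
(B-spline derivative recursion + rational quotient rule), clamped to
the bracketing scan interval, tolerance 1e-10 in `u`, at most 50
iterations, with a bounded golden-section fallback when `g'' ≤ 0`. The
batch variant shares one scan and runs the Newton updates vectorized
across all queries. Against a 100,001-point dense scan the distances
agree to better than 1e-4 cm.

## Guidance force laws

* **Attractive (initialization):** with `r = ‖C(t₀) − D‖`,
  the force is `k_A·d_A·(C(t₀)−D)/r` for `r > d_A` (constant magnitude
  `k_A·d_A`), `k_A·(C(t₀)−D)` for `d_t ≤ r ≤ d_A`, and zero inside
  `d_t`. The two regimes coincide exactly at `r = d_A`. The drop from
  magnitude `k_A·d_t` to zero at the dead-zone boundary is implemented
  literally; a `smooth_dead_zone` flag (default off) instead ramps the
  force linearly to zero at the origin, for haptic hardware that
  dislikes discontinuities.
* **Static (tracking):** `F = k_s·(C(u*) − D)` with `u*` from the
  closest-point projection. At interior minimizers this force is
  orthogonal to the curve tangent — it corrects in the normal
  direction only and exerts no time pressure.
* **Time-dependent (tracking):** `F = k_d·(C(u(t_t)) − D)` where
  `t = t₀ + u(t₁−t₀)` inverts to give the target parameter. The target
  time replays the recording clock from the moment the tracking phase
  began, scaled by `playback_rate` (default 1.0); times outside the
  recording window are clamped with a logged warning. This force has
  both normal and tangential components, enforcing the expert's pacing.
* **Training strength:** all forces are finally scaled by `(1 − v)`,
  `v ∈ [0, 1]`.

The phase machine is monotone: a session starts in initialization and
switches to tracking the first time the probe enters the dead zone
around `C(t₀)`; it never switches back.

No published values exist for `k_A, k_s, k_d, d_A, d_t`; the defaults
(stiffnesses 5 force/cm, `d_A = 1` cm, `d_t = 0.1` cm) are
knee-workspace-scale engineering choices and are clearly configuration,
not constants of the method. Which tracking mode the original
evaluation used is also unstated; both are exposed and `static` is the
default.

## Synthetic data generator

The generator defines the study conditions for everything the test
suite and the acceptance script measure.

* **Expert path:** 8 random waypoints inside 80% of a 10×8×6 cm
  workspace box (knee-joint scale), neighbour-blended by a smoothness
  factor of 0.5, interpolated by a natural cubic spline over a 15 s
  recording and sampled at 30 Hz (the capture rate of the tracking
  rig); rescaled into the box if the spline overshoots. Orientations
  align the probe axis with the path tangent.
* **Tracker noise:** i.i.d. Gaussian position noise, default SD
  0.05 cm per axis — sub-millimetre, appropriate for a calibrated
  close-range stereo rig — and frame dropout with default probability
  0.02 per frame, each dropout repeating the previous output frame and
  marked `held`.
* **Trainee:** a point mass (1 unit) with viscous damping `c`
  (default 8 force·s/cm) pulled toward a noisy view of a target that
  advances along the curve at `speed_factor` × the recorded pacing.
  The pull gain is set to the critical-damping value `c²/4m`, so the
  probe neither oscillates nor crawls; `skill_sigma` (default 0.3 cm,
  0.5 cm for the "novice" cohorts) is the SD of the Gaussian intent
  noise and is the competence dial. Integration is semi-implicit Euler
  at the 30 Hz tracker rate — this is a desk-scale simulation of
  session-level behaviour, not 1 kHz haptic firmware. After the target
  reaches the end of the recording the session runs on (at most 10 s
  extra) until the probe settles inside the guidance dead zone of the
  final point, so the operation time reflects how directly the subject
  finishes. Per-subject RNG streams derive from
  `SeedSequence([master_seed, subject_id])`, making cohorts
  reproducible subject-by-subject.

**What this does and does not show.** The simulated trainee reproduces
the *direction* of the guidance effect — paired sessions show lower
normal path error with guidance than without for essentially every
virtual subject, and the error decreases as the guidance spring
stiffens — because the guidance force genuinely adds curve-restoring
feedback that the noisy operator lacks. It does not model human motor
learning, fatigue, tremor spectra, or retention between sessions, so
the simulated effect *sizes* are not comparable to the human cohort's
33.01%/14.95%, and no operator parameter should be read as an estimate
of any human subject. The human-cohort statistics in this package come
from the packaged reference tables, which are measurement data, not
simulation output.

## Evaluation conventions

Per-session: AVG is the arithmetic mean of the per-sample normal path
errors, SD is the sample standard deviation (n−1; the convention for
freshly computed sessions — packaged table cells are fixture data and
never recomputed), operation time is last minus first timestamp.
Cohort headline: `100 × meanᵢ(1 − withᵢ/withoutᵢ)` over the eight
subjects' second-session rows, the aggregation that reproduces both
published percentages to two decimals; it is invariant to a common
rescaling of both tables. Reported values round half-even to 3 decimals
(cm) and 2 decimals (percent).

## Problem sizes

The default test-suite and acceptance-script workloads use 15 s × 30 Hz
(450-sample) recordings, 15 control points, cohorts of 8 virtual
subjects, 100-pose tracking round-trips, and 100-curve basis sweeps —
sizes at which every documented property is already stable across
seeds.

## Known limitations

* No image-plane marker segmentation: corner pixels are synthesized
  (or supplied); lens distortion is assumed already corrected in the
  given intrinsics.
* Orientation is tracked and stored but not smoothed or guided; only
  position enters the curve fit, the force laws and the error metric.
* Single inspection pass per curve; no stitching of multiple passes,
  no arc-length reparameterization.
* No inferential statistics on cohort comparisons (none are defined
  for the reference protocol), and no tremor metric — the SD row is
  the only dispersion measure.
* No soft-tissue interaction or collision forces; the guidance field
  is the only force environment.
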