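# arthroguide

A desk-scale engine for **experience-based arthroscopic skill training**.
Arthroscopic knee inspection is hard to learn: the joint space is narrow,
visibility is limited, and hand–eye coordination is non-intuitive. One
effective way to transfer an experienced surgeon's skill is to *record*
their inspection trajectory and then *guide* a trainee's hand along it
with a haptic force field while scoring how closely the trainee follows.

`arthroguide` implements that whole pipeline in software, replacing the
cameras and the haptic device with validated synthetic stand-ins:

1. **Stereo marker tracking** — a square fiducial marker of known side
   length, rigidly fixed to the arthroscope, is observed by two CCD
   cameras at 30 frames/s. Each detected set of four corner pixels
   yields the camera-from-marker pose (planar homography + SVD
   re-orthonormalization). The left camera is the reference frame;
   right-camera poses are chained through the fixed transform
   `T_rl = T_mr⁻¹ · T_ml`; when both cameras miss the marker, the
   previous pose is held.
2. **NURBS smoothing and compression** — the recorded points `Q_i` are
   fit by a degree-*p* NURBS curve
   `C(u) = Σᵢ R_{i,p}(u) Pᵢ` with `m < n` control points, where
   `R_{i,p}` is the rational Cox–de Boor basis on a clamped knot vector
   and each sample time maps to the parameter
   `ūᵢ = (tᵢ − t₀)/(t₁ − t₀)`. The first and last control points are
   pinned to the first and last data points; the interior minimizes the
   sum of squared residuals. This filters tracker noise and typically
   compresses the data ~30×.
3. **Force guidance (virtual fixtures)** — three force laws act on the
   trainee's probe `D`:
   an *attractive* force toward the curve start (saturating at
   `k_A·d_A`, linear between the dead-zone radius `d_t` and `d_A`, zero
   inside `d_t`); a *static* force `k_s·ε` along the contour error
   `ε = C(u*) − D` toward the closest curve point; and a
   *time-dependent* force `k_d·e` toward the time-scheduled target
   `C(t_t)`, which also replays the expert's pacing. A training
   strength `v ∈ [0, 1]` scales any force by `(1 − v)`: `v = 0` is full
   guidance, `v = 1` removes it.
4. **Trainee simulation** — a damped point mass driven by a noisy
   "operator intent" toward a target progressing along the curve, plus
   the guidance force, integrated semi-implicitly at 30 Hz.
5. **Skill evaluation** — the *normal path error*: for every trainee
   sample, the shortest distance to the expert curve; summarized per
   session as mean (AVG, cm), sample SD, and operation time (s).
   Cohort tables recorded with and without guidance are compared by the
   mean per-subject relative reduction on second-session rows.

The package ships the published eight-subject reference tables
(with/without force guidance, two sessions each) as fixture data and
reproduces their headline statistics exactly.

## Worked example

```python
import numpy as np
from arthroguide import *
from arthroguide.simulate import subject_seed

# synthetic expert recording: smooth path in a 10×8×6 cm workspace,
# 15 s at 30 Hz, with tracker noise and 2% frame dropout
traj  = generate_expert_trajectory(ExpertPathParams(seed=3))
noisy = add_tracking_noise(traj, TrackerNoiseParams(sigma=0.05,
                                                    dropout_prob=0.02, seed=3))
curve = fit_curve(noisy, m=15, p=3)
print(f"raw samples: {len(noisy)}, control points: {curve.n_control_points}")

# one virtual novice, with and without force guidance (paired seeds)
op = OperatorModel(skill_sigma=0.5, seed=subject_seed(1, 0))
for v, label in [(0.0, "guided"), (1.0, "unguided")]:
    session, t = simulate_session(curve, op, GuidanceConfig(v=v),
                                  seed=subject_seed(1, 0))
    m = session_metrics(normal_path_error(session, curve), 0.0, t)
    print(f"{label:9s} AVG {m.avg:.3f} cm  SD {m.sd:.3f} cm  time {m.time:.2f} s")

# headline statistics of the packaged reference cohort
wo, wi = load_reference_cohort("without"), load_reference_cohort("with")
print(f"error reduction {mean_relative_reduction(wo, wi, 'avg'):.2f}%")
print(f"time  reduction {mean_relative_reduction(wo, wi, 'time'):.2f}%")
```

Output:

```
raw samples: 450, control points: 15
guided    AVG 0.105 cm  SD 0.052 cm  time 15.17 s
unguided  AVG 0.123 cm  SD 0.057 cm  time 15.17 s
error reduction 33.01%
time  reduction 14.95%
```

The guided virtual novice tracks the expert path more closely than the
same novice (same random draws) without guidance; the reference cohort
shows a 33.01% lower mean error and 14.95% shorter operation time with
guidance in the second session.

The same pipeline is available from the shell:

```bash
arthroguide track --rig rig.yaml --seed 3 --out traj.csv   # synthetic stereo capture
arthroguide fit --in traj.csv --m 15 --p 3 --out curve.json
arthroguide simulate --curve curve.json --seed 7 --out-dir run/
arthroguide cohort --without t1.csv --with t2.csv          # prints both reductions
```

Every output embeds the tool version and a hash of the effective
configuration; identical inputs and seeds give byte-identical outputs.

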