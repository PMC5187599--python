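# Methods

`gaitmode` implements a continuous, causal gait-mode recognizer for a
powered ankle-foot orthosis (AFO): from a foot-mounted inertial
measurement unit (IMU) and two foot switches it decides, at every 200 Hz
sample, whether the wearer is walking on level ground, ascending, or
descending — so that swing-phase ankle actuation (dorsiflexor torque for
level/ascent, plantarflexor for descent) can be switched without manual
input and without waiting for the next step.

## Signal front end

The two classifier inputs are vertical foot velocity and sagittal foot
pitch.

**Pitch** is extracted from the per-sample body-to-world quaternion with
the aerospace Z-Y-X sequence, `pitch = asin(2(wy − xz))`, positive
toe-up; the asin argument is clamped to [−1, 1] near the gimbal
singularity.  Orientation is taken as given per sample: on-line attitude
filtering is the IMU's job, not this package's.

**Velocity** comes from world-frame vertical acceleration `a_z` (gravity
included) by cumulative trapezoidal integration of `a_z − g`,
drift-corrected with zero-velocity updates (ZUPT).  A sample is
stationary when `|a_z − g| < ε_g` persists for at least `min_dwell`
consecutive samples (default 5 = 25 ms at 200 Hz, rejecting single-sample
noise crossings).  Contiguous stationary samples form an event; velocity
is pinned to exactly zero across the event, and integration restarts from
zero at each event (this matters: integrating through a long stance with
a biased accelerometer would otherwise leak an offset into the following
swing).  Between consecutive events the accumulated end error is removed
either as a linear ramp over the gap (`linear_detrend`, the default and
standard ZUPT practice: a constant accelerometer bias `b` then leaves at
most `b·T` of residual over a gap of `T` seconds) or as a jump at the
event (`reset`).

`ε_g` is tuned per training trial: the largest value on a 30-point
log grid over [0.01, 2.0] m/s² whose detections all fall inside known
stance windows, so zero-velocity instances only fire mid-stance.  When
noise defeats the accelerometer test during some stance, a fail-safe
fires: any interval with both heel and toe foot switches on that contains
no primary detection contributes its midpoint sample, so every stance
anchors the integrator at least once.

## Network

A feed-forward network maps a 12-element input — velocity and pitch, each
with six tapped delays of consecutive samples (30 ms of context) — through
10 log-sigmoid hidden units to 3 linear outputs.  Targets use a
three-element coding: ascent (1,0,0), level (0,1,0), descent (0,0,1),
undetermined (0,0,0).  Inputs are z-scored with training-set statistics
(m/s and degrees differ by orders of magnitude; conditioning would
otherwise be poor); the constants travel with the model.  At the stream
start the delay line is padded by repeating the first sample, flagged.

Training minimizes `E = α Σ‖t_i − y_i‖² + β E_w`, where `E_w` is the sum
of squares of all 163 weights and biases, by Levenberg–Marquardt on the
Gauss–Newton approximation: damping μ (init 1e−3) is multiplied by 10 on
a rejected step and by 0.1 on acceptance, so the cost at the governing
(α, β) never increases across accepted steps.  α and β are re-estimated
every epoch under the evidence framework.  Note the convention — α
multiplies the *error* term and β the *weight* penalty, the reverse of
the common statement — so the effective number of parameters is
γ = k − 2β·tr(H⁻¹) with H = 2α JᵀJ + 2β I and k = 163, and the updates
are β ← γ/(2E_w), α ← (N − γ)/(2E_D) with N the residual count.  γ is
clipped to [1e−3, k] and the denominators floored at 1e−12 for numerical
safety.  Weights start from a seeded Nguyen–Widrow initialization
(uniform ±0.5, rows rescaled to 0.7·h^(1/n), biases spread over the input
range), which makes training bit-reproducible for a fixed seed.
Stopping: max 300 epochs, infinity-norm gradient below 1e−7, or an
accepted-step cost change below 1e−9.

## Decision layer

Raw outputs are smoothed per element by the first-order low-pass
`ε ẏ̅ + y̅ = y` with ε = 0.02 s, discretized exactly for piecewise-constant
input: `y̅[k] = y̅[k−1] + (1 − e^(−1/(fs·ε)))(y[k] − y̅[k−1])`, seeded with
`y̅[0] = y[0]`.  The filter is a convex combination of past inputs, hence
unconditionally stable and bounded by the input's running envelope.

Each filtered element is binarized against a minimum-Bayes-risk
threshold.  On training data the element's samples split into class 1
("target value 0") and class 2 ("target value 1"), each modeled Gaussian
with sample mean and SD (ddof = 1; SDs floored at 1e−3 so near-noise-free
training data cannot degenerate).  With loss matrix
`L = [[0, λ12], [λ21, 0]]`, default `[[0, 1.0], [0.5, 0]]` (a false
positive costs twice a false negative — the conservative choice for
actuation), the threshold solves `λ12 p(z|w1) = λ21 p(z|w2)`.  Equal SDs
give the closed form `z_o = (μ1+μ2)/2 + σ² ln(λ12/λ21)/(μ2−μ1)`; unequal
SDs give a quadratic whose two roots are the stationary points of the
expected risk — the root with the lower expected risk is kept (the
nearest-to-midpoint root can be the risk *maximum*), preferring roots
inside `(μ1 − σ1, μ2 + σ2)`, with the midpoint as fallback when the roots
are complex.  Ties at the threshold binarize to 1 (fixed for determinism;
unreachable in floating practice).  A plain 0.5 cut is kept behind a flag
for comparison.  The binary 3-vector maps back through the coding; any
combination outside the four defined ones (e.g. two elements high) is
Undetermined.

## Step-level evaluation

Gait cycles run between consecutive debounced heel strikes (OFF→ON of the
heel switch persisting ≥ 10 samples); swing starts at the last toe-switch
release before the next heel strike.  A step's predicted mode is the
label of the longest run of determined samples in
[swing start, next heel strike), ties to the later run; its detection
sample is the first window sample from which the prediction holds without
switching to a different determined label (undetermined gaps do not reset
detection).  Success rate is the percentage of steps whose predicted mode
equals the true mode — a step left Undetermined counts as incorrect, the
conservative reading.  Detection delay, reported for transition steps
(true mode differs from the previous step's) whose new mode was actually
detected, is `100·(detect − swing_start)/(cycle length)` in percent gait
cycle.

## Synthetic gait generator

No public dataset carries this sensor set with mode labels, so the
package ships a seeded simulator that every other module is tested
against.  It emulates two protocols: a stairs bout (3–4 level steps, 6
ascending at 14 cm rise per step, 3–4 level, a turn, 3–4 level, 6
descending, 3–4 level) and a ramp bout (3–4 level, 8–10 up a 6° ramp,
turn, 8–10 down, 3–4 level), at 200 Hz, five subjects × three trials per
scenario with trial 1 the training split.

Each cycle is a stationary flat-foot stance (60% of the stride) followed
by swing.  The swing's vertical trajectory is a minimum-jerk rise/drop to
the next surface plus a sin³ clearance arc (5 cm), chosen so velocity
*and* acceleration vanish at both swing boundaries — the emitted
acceleration is continuous and the ZUPT front end can be validated
against the analytic derivatives exactly.  Swing samples sit on an
interior time grid so lift-off/landing instants coincide with stance
samples.  Pitch blends between surface inclinations (±grade on the ramp,
0 elsewhere) plus a mode-specific sweep peaking in early–mid swing
(level +12°, stair ascent +30°, stair descent −25°, ramp ascent +18°,
ramp descent −12°, scaled ±10% per subject): stepping up demands early
strong dorsiflexion to clear the edge, stepping down a toe-down reach.
Ramp rise per stride is `stride_length · tan(grade)`.  Turns are two slow
level steps (1.5× stride time, reduced clearance), labeled Level since
the protocol assigns them no mode of their own.

White Gaussian noise is added to the emitted acceleration (SD 0.3 m/s²)
and pitch (SD 1.0°) — levels at which the stationarity threshold needs
actual tuning and the foot-switch fail-safe occasionally fires — while
the truth tracks stay clean.  Per-subject parameters (stride time
1.1 ± 0.1 s, stride length 1.2 m ± 10%, clearance and sweep ± 10%) are
drawn once per subject and held across trials.  Everything derives from
`(seed, scenario, subject, trial)` through independent generator streams,
so trials are bit-reproducible.

**What the simulator does not capture** — and hence what passing tests do
not show about real data: orientation-estimate drift and attitude error
(quaternions are built directly from the true pitch plus white noise, so
there is no correlated low-frequency error in `a_z`), impact transients
at heel strike, fore-aft/mediolateral dynamics, foot-switch bounce beyond
simple debouncing, within-trial fatigue or speed drift, and real
inter-subject kinematic diversity.  Mode classes are separable by
construction (per-step swing-mean features ≥ 2 pooled SDs apart), so the
near-perfect synthetic success rates certify the pipeline's correctness,
not its field performance; detection delays on synthetic data (a few
percent of the gait cycle) are likewise optimistic because mode-specific
cues appear from early swing.

## Problem sizes and defaults

The reproduction study uses the full protocol: 5 subjects × 3 trials × 2
scenarios (≈ 27 steps and 35 s per stairs trial, ≈ 31 steps per ramp
trial at 200 Hz), training per subject on trial 1 (≈ 7000 samples, LM
with full Jacobian, ≤ 300 epochs) and testing on trials 2–3.  On one CPU
this completes in a few minutes.  Unit tests use the same generator with
fewer subjects and capped epochs.

## Known limitations

* The recognizer is subject-specific by default, mirroring the study
  design; `run_study(..., pool_subjects=True)` trains one model on all
  training trials but is not the reported configuration.
* The quaternion→pitch formula is a declared convention (Z-Y-X, toe-up
  positive); any IMU whose firmware uses a different sequence needs its
  quaternions converted upstream.
* Thresholds assume Gaussian class densities of the filtered outputs;
  heavily multimodal outputs (e.g., a network trained on conflicting
  labels) would violate that assumption.
* The tapped-delay spacing is fixed at consecutive 200 Hz samples; other
  sampling rates rescale the temporal context accordingly.
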