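# Methods

## EMG amplitude estimation

EMGσ is estimated by a five-stage causal cascade (notch 60 Hz/1 Hz,
highpass 15 Hz order 5, full-wave rectification, Chebyshev-I lowpass 16 Hz
order 9 / 0.05 dB, decimation 2000 → 100 Hz, critically damped 1 Hz
smoother). Conventions the published parameterisation leaves open were
fixed as follows:

- **Notch bandwidth** is the −3 dB bandwidth (quality factor Q = f₀/bw).
- **Critically damped smoother** is a cascade of two identical one-pole
  sections (double real pole). The pole is solved in closed form so the
  *cascade* magnitude is −3 dB at exactly the configured cutoff; each
  section is `H(z) = (1−a)/(1−a z⁻¹)` with unity DC gain.
- **Rectification** is the absolute value.
- **Decimation** takes every 20th sample after the 16 Hz lowpass; a frame
  is emitted after each full group of 20 raw samples, so batch output
  length is ⌊N/20⌋ and the streaming path is bit-identical to the batch
  path by construction (both run the same recursions with carried state).
- **Initial state** is all-zero (cold start). Calibration trims the first
  second of every segment, which absorbs the startup transient.
- Post-smoothing undershoot (possible through Chebyshev ringing around
  sharp drops) is clamped to zero, since EMGσ is an amplitude.

Stage stability is checked at design time from the section denominators
(poles strictly inside the unit circle); measured responses put the notch
minimum, the highpass −3 dB point, the smoother −3 dB point and the
passband ripple at their configured values to well within 0.01 Hz /
10⁻³ dB.

## Calibration model

The EMGσ–force map is linear with an intercept column: the intercept
absorbs the rest-level EMGσ (noise floor), which otherwise biases the
force estimate at rest. The published description does not mention an
intercept; it is on by default here and can be disabled (`FitSpec(bias=False)`).

The fit is the truncated-SVD pseudo-inverse: singular values are retained
iff `sᵢ/s_max ≥ Tol` with Tol = 0.01 (removal on strict inequality). The
rest segment is replicated eight times in the design — equivalent to
weighting — so one 10 s rest balances eight 10 s active segments.
Per-type RMSE pools squared errors over both DoF outputs; rest replicas
are identical rows, so the per-type value equals the value over unique
frames, while the overall RMSE pools all (replicated) rows — the same
convention the selection objective uses.

Two-DoF segments target both engaged directions at ±30 %MVC
simultaneously; unused DoFs target zero. Signs: hand + = open/extension,
− = close/flexion; wrist + = pronation/radial, − = supination/ulnar.

**Backward stepwise selection** refits with each remaining electrode
removed and permanently drops the one whose removal yields the lowest
overall training RMSE (the intercept is never a candidate; ties break
toward the lowest channel index, making runs reproducible). Selection and
fitting use the same 90 s recording — there is no hold-out, matching the
intended fitting workflow. Under truncation the training RMSE is not
mathematically guaranteed monotone as channels are removed, but it is in
practice and is asserted as a property test.

## Controllers

Order of operations is fixed: resting thresholds → co-activation gate →
velocity map.

- **Resting thresholds** are four per-direction hard dead zones
  (default 10 %MVC); values at the threshold pass.
- **Co-activation gate**: with a = atan2(min(|h|,|w|), max(|h|,|w|)), the
  smaller-magnitude component is zeroed iff a < α (default 25°). The
  equal-magnitude diagonal (a = 45°) always passes. The geometric (angle)
  formulation is used; the equivalent ratio statement can be read with
  either orientation, and the angle form matches the published gating
  diagram.
- **Velocity map**: per DoF, zero stays zero; |force| maps linearly from
  its direction's resting threshold (→ plant minimum actuation speed, 8
  mm/s for the gripper, 0 for the wrist) to the saturation effort
  (default 50 %MVC → maximum speed), clamped beyond. Axis inversion flags
  apply last. The 8 mm/s minimum reflects the gripper's nonzero minimum
  proportional speed; whether physical hardware adds its own dead-band is
  unknown, so all thresholding lives in this map.

**SeqCon** scales the two chosen channels by `30 / mean(EMGσ)` over each
channel's dedicated trimmed calibration segment (extension for the
extensor electrode, flexion for the flexor). The net drive is the
algebraic difference extensor − flexor after per-channel dead zones. The
co-contraction detector accumulates time while both scaled channels exceed
their co-contraction thresholds; reaching the window (default 50 ms,
valid range 30–100 ms, rounded to 10 ms frames) toggles the active DoF
exactly once. Choices the published description leaves to the fitter:

- Default co-contraction thresholds sit midway between 30 %MVC and the
  session-wide peak scaled value (there is no dedicated co-contraction
  segment to measure a peak from); all thresholds are editable, as they
  are subject-chosen in practice.
- After a toggle, a refractory (default 300 ms, may be 0) forces zero
  output, and detection re-arms only once the co-contraction condition has
  broken — one sustained co-contraction produces one toggle. Output during
  detection-in-progress is *not* suppressed by default (movement before
  the trigger is the observed hardware behaviour); a flag enables
  suppression.
- Timers run at the fixed 100 Hz loop (dt = 10 ms).

With these rules the toggle count on any input equals a run-length
computation (one toggle per maximal supra-threshold run whose
non-refractory length reaches the window), which the tests exploit as an
independent brute-force reference.

## Virtual plant

First-order kinematics at 100 Hz: aperture integrates the hand command and
clamps at the travel limits (command absorbed at the stop); wrist angle
integrates unbounded. Speed envelope: 8–200 mm/s gripper, 28 rpm
(168 °/s) wrist. The 0–100 mm aperture range is a configurable assumption
(the gripper's travel is not published). No motor dynamics, backlash or
grip-force model.

## Synthetic sessions

The generator realises the standard amplitude-modulation model of surface
EMG: per channel, a unit-variance band-limited Gaussian carrier
(20–450 Hz, order-4 Butterworth bandpass, independently seeded per
channel) is multiplied by the envelope
`noise_floor + gains · efforts(t)`, plus optional additive 60 Hz
interference. Efforts are nonnegative drives along four primitive
directions; the signed ground truth is (hand⁺−hand⁻, wrist⁺−wrist⁻).

- **Electrode gains** emulate equally spaced circumferential electrodes:
  each direction peaks on a distinct contiguous arc with cosine falloff
  (arc offset drawn from the seed). Each informative electrode's gain row
  is normalised to a per-electrode sensitivity drawn from U(0.02, 0.03)
  amplitude-units/%MVC, so relative direction tuning comes from arc
  position while every informative electrode genuinely sits over active
  muscle. Designated noise channels get zero gain (pure noise floor,
  U(0.003, 0.008)), emulating electrodes over electrically silent tissue.
- **Effort profiles** ramp over 0.5 s (raised cosine), hold at the 30 %MVC
  target and ramp off; the edge trim (1 s) removes the ramps from the
  design. A slow multiplicative wander (one-pole filtered noise at
  ~0.5 Hz, relative std 0.1 by default) emulates a subject's inability to
  hold a fixed force without feedback.
- **Per-channel amplitude wander** (default relative std 0.08, ~0.5 Hz)
  models the fact that individual muscles do not track a rank-4 effort
  vector exactly (motor variability, force sharing, electrode coupling
  drift). Besides realism, this matters numerically: without it the
  90 s design matrix is numerically rank ≈ 5 (four directions + common
  mode) and channel-contrast singular values hover at the truncation
  tolerance, making selection refits erratic.
- All randomness stems from one session seed via independently spawned
  sub-streams (carriers, effort wander, channel wander), so sessions are
  byte-reproducible.

**What the generator does not emulate**: motor-unit physiology, electrode
shift and lift-off, fatigue, crosstalk dynamics, movement artifact beyond
what the highpass removes, and task-dependent co-contraction patterns.
Passing recovery tests therefore shows the *pipeline* is correct and
well-conditioned under the stated signal model, not that human subjects
would achieve these errors; human calibration RMSEs are several-fold
larger and task performance cannot be predicted from this model at all.

## Problem sizes and test conditions

Tests and the acceptance script use full 90 s sessions at 2000 Hz with 16
channels (the calibration geometry is part of the method), ten seeded
mixings for the selection-recovery study, 1000 random short sequences for
the toggle-count study, and 20 random 100×16 systems for the
pseudo-inverse oracle. The "noise-free" recovery condition sets effort
jitter, channel wander and interference to zero while keeping the
stochastic carrier — the carrier *is* the EMG — so its < 1 %MVC bound
measures amplitude-estimation error alone; the default condition keeps all
wander on.

## Known limitations

- MapCon is semantically identical to DirCon at run time (the mapping
  lives in the calibration labels and inversion flags), so nothing here
  measures the *human* distinctness of wrist actions that motivates
  MapCon.
- EDF input is not supported; the raw-EMG CSV dialect is the interchange
  format.
- The greedy selection optimises training RMSE only; no cross-validation.
- The co-contraction threshold heuristic is a default, not a claim about
  how fitters choose thresholds.
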