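# Methods

## Signals and conventions

A recording is a set of 9-axis MARG streams (acceleration in g, angular
rate in °/s, magnetic field in µT) at a nominal 100 Hz, one stream per
sensor placement (wrist / upper arm × left / right). Validation bounds are
the sensor's measuring ranges: ±4 g, ±2000 °/s, ±1200 µT. The sensor x-axis
lies along the forearm, so gyroₓ is the pronation–supination rate.

Quaternions are scalar-first and sensor-to-earth (`v_earth = q ⊗ v_sensor
⊗ q*`); the earth frame is right-handed, z up, x along the horizontal
projection of magnetic north. Euler angles are intrinsic yaw–pitch–roll
with *pitch* defined as the elevation of the sensor x-axis above horizontal
— the quantity that rises by ~45° when the arm is lifted for the task.
The magnetic reference used by the simulator is (20.7, 0, −44.4) µT,
a mid-latitude field of ~49 µT with 65° inclination.

## Orientation estimation

Raw channels pass a zero-phase (forward–backward) 2nd-order Butterworth
low-pass, default cutoff 10 Hz: hand-turning fundamentals stay below
~8 Hz, and zero-phase filtering leaves zero-crossing and boundary times
unshifted. Cutoff and order are configuration parameters.

Fusion is the original Madgwick gradient-descent complementary filter for
MARG data: the quaternion rate from gyroscope integration is corrected by
β times the *normalized* gradient of an objective that aligns predicted
gravity and magnetic field with the measured directions, including the
magnetic-distortion compensation step (the measured field is rotated to
earth and its horizontal component collapsed onto x before the gradient is
formed). β defaults to 0.041. With β = 0 the filter reduces exactly to
gyro quaternion integration. A zero-norm accelerometer or magnetometer
sample degrades that step to gyro-only (logged), never an exception.

The first quaternion comes from TRIAD-style accelerometer/magnetometer
alignment averaged over the first ~0.5 s — the protocol starts at rest, and
a single magnetometer sample at realistic noise can be tens of degrees off
in heading.

Convergence behaviour worth knowing: because the corrective step has fixed
magnitude β (normalized gradient), static orientation error decays at a
bounded rate of about 2β rad/s ≈ 4.7 °/s. At β = 0.041 an initial error of
15° is removed to under 1° within 5 s; 30° needs roughly 9 s. This is a
property of the filter itself, not of the implementation; the test suite
asserts the attainable 15° contract and exercises the 30° case in the
end-to-end acceptance checks.

Resampling to the 60 Hz animation rate is component-wise cubic-spline
interpolation of the (sign-continuous) quaternion components followed by
renormalization; for the slow rotations of this task the deviation from
geodesic (slerp) interpolation is far below a degree, and slerp serves as
the test oracle rather than the implementation.

## Phase segmentation

Seven phases in fixed order: RE1, LI, HO1, PS, HO2, LO, RE2. A clinical
system trained on labeled videos could learn this split; here a
deterministic threshold state machine recovers it so that results are
reproducible without any training data:

* **PS** is found from a moving-RMS envelope (window 0.25 s) of gyroₓ.
  Regions above a threshold (configured 30 °/s, adaptively lowered to 10%
  of the observed envelope peak — never below 10 °/s — so a fading,
  barely-performed sequence is not truncated) are merged across
  sub-threshold gaps up to 3 s, which bridges rhythm interruptions; the
  longest merged run is PS. Its edges are then refined to where the
  smoothed |gyroₓ| (0.2 s mean) leaves the noise floor; the edge level is
  2.5 °/s or 3.5× the measured quiet-phase floor, whichever is larger, so
  added sensor noise cannot masquerade as activity. A recording whose
  envelope never exceeds the configured threshold raises a segmentation
  error carrying the envelope for diagnosis.
* **LI / LO** are found from the pitch series: the crossing of rest pitch
  + 20° anchors each ramp, and the boundary is walked back/forward to where
  the smoothed pitch rate leaves a ±5 °/s band — the 20° crossing itself
  sits mid-ramp and would misplace the boundary by several tenths of a
  second.
* RE1, HO1, HO2, RE2 fill the gaps. If a hold is squeezed below one sample
  it is emitted as a minimal one-sample interval so the seven-label
  contract always holds. Intervals are 0-based and half-open.

On the simulator corpus (all five severities, default noise) every
recovered boundary falls within 0.1 s of ground truth; the acceptance
suite asserts ±0.2 s.

## Oscillation features

Zero crossings of the PS-phase gyroₓ are detected with a Schmitt trigger
(hysteresis band 10% of the robust peak) and sub-sample interpolation; an
oscillation is the interval between consecutive crossings (one hand turn),
and a *pair segment* spans two adjacent oscillations, so n oscillations
yield exactly n − 1 segments and every interior oscillation belongs to two.

Per segment: maximum |gyroₓ| (turns alternate sign); the cumulative
rotation angle by trapezoidal integration, its peak-to-peak range and its
75th percentile (linear-interpolation percentile); and the R² of
sum-of-sines fits with one and three terms. Fits are damped nonlinear
least squares (Levenberg–Marquardt with analytic Jacobian) from a
deterministic start: base angular frequency π / median crossing-to-crossing
period, amplitude RMS·√2, phase 0; for n = 3 the extra terms start at 2×
and 3× the base frequency with a tenth of the amplitude. A second
deterministic n = 3 start seeded from the converged n = 1 fit is also tried
and the lower-residual optimum kept — this guarantees the nested-model
property R²(3) ≥ R²(1), which a single start can violate on noisy segments.
Iterations are capped at 200; hitting the cap flags the fit and reports R²
at the best iterate. Amplitudes are canonicalized non-negative and sorted
descending, phases wrapped to [−π, π).

The eight features: `mean_angRate` (mean of per-segment peak rates),
`median_rotAngle` (median peak-to-peak rotation angle), `upQuart_rotAngle`
(mean of per-segment 75th percentiles of the rotation-angle trajectory),
`ratioQ13_angRate` / `ratioQ13_rotAngle` (mean of the quantity over the
first ⌊m/3⌋ segments divided by the mean over the last ⌊m/3⌋; the remainder
goes to the excluded middle), and `std_rsquare_1n`, `mean_rsquare_3n`,
`std_rsquare_3n` (sample SD / mean of the per-segment R² values). With the
first-to-last orientation, slowing or shrinking over the test produces
ratios *above* one. Additional per-recording features can be registered at
runtime (`register_feature`), matching the idea that these eight are a
selected subset of a larger family.

Interpretation choices that were genuinely open, isolated behind single
functions: `upQuart_rotAngle` uses the percentile of the rotation-angle
*trajectory* (not of per-turn peak angles); `mean_angRate` uses the
per-segment *maximum* rate (not RMS — the two are nearly equivalent in
practice); the thirds ratios are first/last (a competing reading would
invert them; the chosen one makes decrement > 1 and matches the positive
severity correlation of the speed ratio).

## UPDRS classification

Feature selection is best-first forward hill-climbing with backtracking
over subsets, scored by the correlation-based merit
k·r̄_cf / √(k + k(k−1)·r̄_ff) (mean absolute feature–class vs
feature–feature Pearson correlation); the search stops after 5 consecutive
non-improving expansions and is deterministic.

The tree is C4.5-style: binary numeric splits at midpoints between sorted
distinct values, chosen by information-gain ratio (minimum leaf size 2),
post-pruned by subtree replacement using the pessimistic (upper-confidence)
error estimate at confidence factor 0.25. Ties break by feature name, then
lower threshold, so identical data and hyperparameters give byte-identical
serialized models (versioned JSON). Class imbalance is not corrected by
default; a class-weight hook exists but is off. Prediction walks the tree;
a missing feature raises an error naming it.

## The motion simulator

The generator builds ground truth first and derives sensors from it:

* Roll profile (PS): cosine-eased alternating turns from the palm-vertical
  hold posture to a supination target (+120° × envelope) and a pronation
  target (−30° × envelope). Per-turn envelope decays by the decrement
  coefficient from the decrement-onset turn; turn durations follow from the
  per-turn peak rate with lognormal rhythm jitter; interruptions are pauses
  inserted at randomly chosen turn boundaries. Pitch ramps 0 → 45° during
  LI and back during LO.
* Quaternions from (roll, pitch); ideal body-frame angular rate by
  quaternion differentiation (ω = 2 q* ⊗ q̇); ideal accelerometer as rotated
  gravity; ideal magnetometer as the rotated reference field; then additive
  i.i.d. Gaussian noise (defaults 0.02 g, 2 °/s, 5 µT). Parameter
  combinations that would exceed the sensor ranges abort before noise.
  The accelerometer carries no linear-acceleration term: for a wrist sensor
  near the forearm axis during this task the tangential component is
  second-order, and omitting it keeps gravity exactly recoverable.
* The upper-arm trace lifts at 35% of the forearm pitch with a small smooth
  sway and no roll.

Severity classes map to parameter bands that follow the clinical rubric
ordinally — interruption counts 0 / 1–2 / 3–5 / 6–9 / 8–12, speed factors
1.0 / 0.85 / 0.68 / 0.49 / 0.22, decrement onset end → midway → start, and
class 4 at 20% amplitude ("barely performs"). Interruption *duration*
grows with severity (0 / 0.25 / 0.45 / 0.8 / 1.0 s nominal): mild disease
hesitates briefly, severe disease freezes — this also keeps the rhythm
feature's growth across classes driven by a mechanism that does not
saturate. The numeric bands are generator conventions chosen to realize
the rubric's ordinal wording; they are documented here precisely because
they are conventions, not published values.

What the simulator does *not* emulate: tremor, gyroscope bias drift
(a drift toggle exists for stress tests but is off), magnetometer hard/soft
iron distortion, linear acceleration, biomechanical coupling between arm
segments, and rater subjectivity. Tests passing on this corpus therefore
show that the pipeline recovers the structure this model generates — clean
severity separation (the synthetic classes are more separable than clinical
populations, where class distributions overlap heavily), not clinical
accuracy.

## Agreement statistics

Confusion matrices are 5×5 with reference on rows. Weighted rates follow
the convention of averaging per-class recall, false-positive rate
(FP / all non-class reference items) and precision with reference-support
weights. Weighted kappa is κ_w = 1 − Σw·o / Σw·e with disagreement weights
|i−j|/4 (linear, default) or ((i−j)/4)² (quadratic); chance proportions
come from the raters' marginals. Missing ratings are deleted pairwise.
Degenerate cases: two identical constant raters return 1.0 with a warning;
two different constant raters return the defined limit with a warning.
Reports always name the weighting used, since the choice changes the
number.

## Animation export

Side detection integrates gyroₓ over PS and compares the excursions in the
two directions; supination dominates (~120° vs ~30° from the hold
posture), and its sign identifies the arm given the along-forearm axis
convention. Excursions symmetric within 10° return "undetermined" and the
caller must supply the side. The exported stream holds, per 60 Hz frame,
the upper-arm quaternion and the forearm quaternion re-expressed relative
to it (q_upper⁻¹ ⊗ q_lower), which is the portable contract for a skeleton
whose forearm bone inherits the upper-arm bone's motion.

## Numerical notes and limitations

* Unit norm is enforced after every public quaternion operation (tolerance
  1e-6); quaternion streams are kept sign-continuous before splining.
* Gimbal proximity (|pitch| > 89.9°) is flagged on Euler extraction; values
  are still returned. The task keeps pitch near 45°, far from the
  singularity.
* Duplicated or non-increasing timestamps are rejected outright rather than
  averaged — loud failure over silent repair.
* Problem sizes: the end-to-end tests use a corpus of 5 classes × 100
  recordings (~20 s each at 100 Hz); the reproduction script uses 5 × 20.
  These sizes give stable class means and held-out splits while keeping a
  full run in the minutes range.
* The decision tree is trained and evaluated on recordings from the same
  generator; no subject-level structure exists, so no subject-wise split is
  needed (clinical data would require one).
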