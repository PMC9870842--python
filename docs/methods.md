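# Methods

This note documents the models implemented in `interceptsim`, the choices
made where the design was genuinely open, and what the synthetic pipeline
does and does not establish about real data.

## Coordinate conventions and units

Positions are millimetres, lateral, with the screen centre as origin and
rightward positive; times are seconds. Targets are rendered at 120 Hz
(frame interval 1/120 s ≈ 8.33 ms); the finger is sampled at 500 Hz (2 ms).
A per-frame step of *s* mm corresponds to a step velocity of 120 *s* mm/s.
Only the lateral target coordinate is modelled; the vertical position of the
target on the screen plays no role in any analysis.

## Target generation

* **Random walk** — each frame the target steps ±1.67 mm (1/6 of the 10 mm
  target radius; ±20 cm/s) with probability ½. Start position 0.
* **Drifting walk** — per-frame steps drawn i.i.d. from a two-point scheme.
  Variability levels map to equiprobable per-frame velocities
  {60}, {50, 70}, {40, 80} and {25, 95} cm/s; all average 60 cm/s.
* **Initial-speed prefixes** — the first 12 steps are all 3.33 mm (slow,
  start −180 mm) or all 6.67 mm (fast, start −220 mm), so every target is
  140 mm left of centre after 100 ms; later steps follow the chosen scheme.
* **Constant acceleration** — eight kinds: direction (±) × acceleration
  along the motion (±400 mm/s²) × speed class. Slow targets start 300 mm
  and fast targets 400 mm from the centre, on the side opposite their
  motion. Initial speeds solve d = v₀·0.7 + ½a·0.7² with d = offset +
  300 mm, i.e. every target is 300 mm past the centre (325 mm from the
  approached edge of the 1250 mm screen) at 700 ms. The printed table of
  initial values was not legible in the source material, so these values are
  reconstructed from the stated constraints; the reconstruction reproduces
  the quoted ≈14 cm/s fast-minus-slow speed difference exactly
  (100 mm / 0.7 s). Per-frame step velocities are evaluated at frame
  midpoints so that the discrete positions match the continuous kinematics
  exactly (this keeps the 700 ms constraint exact at frame 84). A
  trajectory that leaves the screen before its last frame is flagged
  `truncated` rather than clipped.
* **Sessions** — 168 trials in 17 blocks: 9 reference blocks (each kind
  once, shuffled) alternating with the 8 grouped blocks (4 kinds × 3,
  shuffled; pair order randomised). The replication scenario uses
  rightward-only targets in alternating all-accelerating /
  all-decelerating 12-trial blocks (slow and fast kinds, 6 repeats each —
  the source experiment's exact speed composition is not specified, so the
  two rightward kinds are balanced).

## Aiming model

The hand aims at the target position seen δ = 100 ms earlier, extrapolated
with the current velocity estimate to the anticipated tap time. δ is
implemented as exactly 12 frames. The velocity estimate is a leaky
integrator updated once per displayed frame, including frames during the
reaction time, with weight w = 0.02 per frame (0.15 for the fast variant);
it takes ⌈ln 0.5 / ln 0.98⌉ = 35 frames ≈ 292 ms to get halfway to a new
constant value. The estimate carries across trials: each trial starts from
the previous trial's final value. At the start of a session it is
initialised to the scheme's mean velocity for unidirectional (drifting)
designs and to 0 for the acceleration design, whose directions alternate;
the first-trial choice decays with factor 0.98 per frame and is negligible
after a handful of trials. The predicted tapping error assumes the aim
point is reached exactly — motor noise lives only in the finger synthesiser,
never in the error model.

## Error learning

Spatial (mm) and temporal (s) aim corrections start at (0, 0) each session
and update after every trial in all block types: retention (×0.95) is
applied first, then 25% of the signed spatial error (15% of the timing
error) is subtracted, exactly in that order. The temporal correction only
extends the extrapolation horizon; it does not shift the simulated tap
time. The timing error is the time at which the target passed — or, by
linear extrapolation at its last step velocity, would have passed — the
tapped position, minus the tap time. If a decelerating target stops short
of the tapped position the signed time of closest approach is used and
flagged (`undefined_crossing`); the flag never fires for the eight standard
trajectory kinds, whose speeds stay positive throughout a trial.

## Session simulation

The original analysis resampled the durations of real trials. Those
recordings are not bundled, so trial durations (target onset to tap) are
drawn from a truncated normal combining each experiment's reported
reaction- and movement-time means, with SDs combined in quadrature
(drifting-jitter design: 209 ± 17 + 280 ± 36 ms; acceleration design:
239 ± 21 + 260 ± 40 ms), rounded to frames and clipped to [24, 120] frames.
`TapTimeModel.shifted(±0.02)` provides a sensitivity variant: a ±20 ms
shift in mean duration moves the acceleration-design mean signed error by
roughly ∓/±0.5 mm (longer trials give the slow accumulator more stale
velocity to drag along). This stand-in is the main known source of
quantitative discrepancy: with the slow (2%) accumulator the simulated mean
ignoring-acceleration-signed error converges to ≈6.8 mm, whereas a mean
duration ≈30 ms longer — plausible for right-skewed trial-level durations
summarised by per-participant medians — would give ≈8.2 mm. The fast (15%)
variant is insensitive to this (≈4.0 mm either way).

Errors in the acceleration design are signed positive when consistent with
ignoring the acceleration (ahead of decelerating, behind accelerating
targets). Learning curves bin the 12 trials of each grouped block into
three sets of 4 consecutive trials, take medians within a simulated
participant and average across participants; reference blocks contribute a
single pooled median. The mean signed error is reported over all trials;
the reference-only variant is available via `mean_signed_error(...,
reference_only=True)` and differs by well under the Monte-Carlo spread.

## Finger synthesis

Each target step pulls the finger toward the displaced position with a
100 ms latency, via either a minimum-jerk correction (completes exactly in
the remaining time T) or a mass-spring-damper with damping b = 75 s⁻¹ and
stiffness k = 3800 − 16·T[ms] s⁻², frozen per step at that step's T. The
initial conditions x(0) = D, ẋ(0) = 0 with response velocity −ẋ are the
minimal reading of "response to a displacement D" (the source does not
state them). The stiffness law crosses zero near T = 237 ms, so the
synthesiser freezes k at its T = 150 ms value for steps with more time
available; the response still runs for the full available time, which lets
corrections for early steps settle completely while leaving the
characterised vigour range (T ≤ 150 ms) untouched. Step inputs are each
step's deviation from the scheme's mean step; the mean path is carried by a
minimum-jerk transport of the printed reach amplitude (250 mm; 300 mm for
the acceleration design) between movement onset and the tap. White
Gaussian positional noise (SD 0.5 mm per sample default; tests mostly use
0.2 mm) is added to the lateral channel — small against the 3.33 mm split
signal so that recovery tests stay sharp. The vertical channel is a smooth
40 mm lift returning to the screen with a nonzero approach velocity, so the
impact produces a three-sample acceleration transient of ≈180 m/s² (the
detector threshold is 50 m/s²); a `gentle_landing` variant lands with zero
approach velocity to exercise the height-minimum fallback.

## Response analysis

Savitzky–Golay smoothing fits a second-order polynomial to the 9 samples
(±8 ms) around each sample; position and velocity are the polynomial and
its derivative at the centre. Edges refit the boundary polynomial
(`mode="interp"`); the filter reproduces quadratics exactly. Tap detection
takes the first sample whose three-sample displacement-difference
acceleration away from the screen exceeds 50 m/s² while the finger is
within 5 mm of the screen and was approaching it; if no crossing exists the
minimum height after the reach apex is used (flagged `z_minimum`); a finger
that never comes within 5 mm raises a no-tap error. Exclusion rules: taps
later than 700 ms after target onset, and marker gaps longer than 20 ms
(shorter gaps are linearly interpolated). Step times are quantized to
target frames; analysis curves live on the 500 Hz grid; tapping errors use
the target position linearly interpolated within the tap's frame. Response
curves are tap-aligned means; each trial contributes only samples it
actually has (no extrapolation), and cells with an empty side are masked.
The response latency estimator takes the first crossing of 25% of the
curve's peak, searched from the step time onward — on synthetic data it
recovers the generative 100 ms latency within one frame. Gains divide the
velocity difference by the step-size difference between the sorted sets
before averaging across participant-analogs and taking the peak.

## Numerical and design notes

* One seeded generator drives each simulated session; sub-streams are
  spawned per session so sessions are reproducible in isolation, and
  identical seeds give bit-identical results.
* Model parameters (w, retention, learning rates, δ) are plain config
  fields defaulting to the published values; they were stated to be chosen
  informally rather than fitted, so no fitting machinery is included.
* The step-sorted split uses the midpoint of the observed step options as
  the high/low threshold; exact-midpoint steps (possible only in the
  zero-variability scheme) belong to neither set.
* Trial durations shorter than the 12-frame delay cannot occur (the
  truncation floor is 24 frames); `predicted_tap_error` raises on them.

## What the synthetic data do and do not show

The generators emulate the stimulus statistics (step schemes, block
structure, kinematic constraints) and the response dynamics of the two
printed movement models, with idealised noise. They do not emulate:
movement-time adjustments to step size, visual feedback after the tap,
hardware artefacts (marker dropout is injected only synthetically in
tests), or the empirical duration distribution (see above). Passing tests
therefore establish that the pipeline is internally correct — it recovers
the latency, vigour scaling and error patterns that the generative models
imply — not that those models fully describe human data. The published
human-data quantities (hit rates, empirical response peaks) require the
original recordings and are out of scope.
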