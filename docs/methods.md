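# Methods

`novelfp` quantifies spatial-novelty coding in continuous cortical LFP
recorded during a visual oddball paradigm with simultaneous head and eye
tracking, and ships a synthetic-session generator whose planted structure
lets every stage be validated end to end.  This note documents the models,
the numerical choices, and what the simulations do and do not establish.

## The paradigm and the response-intensity statistic

A session presents a white triangle at one frequent grid position (the
*standard*) and one rare position (the *deviant*, ~1/10 of trials), 2 s per
stimulus with a 5 s black-screen interval.  Sessions hold 200 trials with
exactly 20 deviants.  Trial groups of interest besides Standard/Deviant:
**First10** (the first ten trials of a session, unadapted), **1After** (the
standard immediately following a deviant), and the gaze-derived **Left**,
**Right** (head angle beyond ±15°) and **FirstView** (head angle ≥ 5° away
from every previous trial's angle) groups.

Per trial, the 80–580 ms post-onset window is cut from the raw voltage,
reduced to 400 Hz by averaging non-overlapping sample blocks (exactly 200
points when the acquisition rate is a multiple of 400 Hz — block averaging
is used rather than decimation for its implicit anti-aliasing and exact
sample count), and discarded if any sample in the window exceeds 900 µV in
magnitude.  Because evoked shapes vary across animals and probe placements,
response strength is measured as the projection onto a first principal
axis rather than by a fixed feature:

* each of 100 repeats takes **all** retained deviant trials plus an equal
  number of randomly drawn standards, centres those rows on their mean and
  extracts the leading axis (SVD);
* axes are sign-aligned to the first repeat before averaging (a PCA axis is
  defined only up to sign; without alignment the average would cancel);
* the averaged, renormalised axis is finally oriented so the mean deviant
  score is at least the mean standard score, with the sign recorded so the
  spatial-control flip rule can refer to the raw direction.

Group scores are normalised by the standard distribution,
`nPC1_X = (mPC1_X − mPC1_Std) / sPC1_Std`, with the Standard reference pool
excluding the first ten trials; `nPC1 > 2` is the session-level
significance convention.  The analysis channel, when not specified, is the
channel with the largest across-trial standard deviation of the window
mean — a deterministic stand-in for manual curation.

## Permutation inference

Within a session the test statistic is the absolute distance between the
test-group mean score and the standard-pool mean; the null redraws a group
of the same size from the pooled trials (10,000 draws, +1-corrected p, so
the smallest reportable level is 1/(n+1) ≈ 10⁻⁴).  The standard pool always
excludes the first ten trials and any trials belonging to the test group
itself, so compared groups are disjoint.  Across sessions the same scheme
shuffles session labels between two sets of per-session scalars; paired
designs pass difference vectors.  Exceedance counting uses a 10⁻⁹ relative
tolerance: a permutation that redraws the observed grouping recomputes the
same distance along a different floating-point path, and a strict `>=`
would drop a true tie over a last-ulp difference.

**A calibration caveat, measured deliberately.** The principal axis is fit
*using the trial labels* (all deviants enter every resampling repeat), but
the permutation null reuses the fixed scores without refitting.  On
effect-free synthetic sessions this inflates the trial-shuffle test's
rejection rate to roughly 0.07–0.10 at nominal 0.05; scoring the same null
sessions on a label-free fixed axis restores 0.050 exactly (200-session
control experiment), which pins the inflation on the label-dependent fit,
not on the resampling machinery.  The `nPC1 > 2` convention is, by
contrast, strongly conservative on null sessions (observed rate 0.0 over
400 sessions).  Users who need exact within-session type-I control should
treat borderline permutation p-values near 0.05 with caution or refit the
axis per permutation at ~100× the cost.

## Gaze geometry

Head direction is the bearing of the caudal→rostral keypoint pair,
averaged circularly over frames from stimulus onset to +400 ms, and
mean-zeroed across trials (the two-point bearing is the deterministic
reading of a rostral-caudal track; a circular mean avoids wrap artefacts).
Keypoints below a likelihood threshold (default 0.9) are dropped; trials
without a single valid frame are excluded from angle analyses with a
warning.

Eye direction assumes a spherical eye centred in its socket: with the
socket centre (least-squares circle through the annotated outline) at the
origin and radius r, the raw angles are `ψ_k = arccos(k/r)` for the fitted
pupil-centre coordinates k ∈ {x, y}; the argument is clipped to [−1, 1]
because noise can push the fitted centre marginally outside the circle.
`[φ_x, φ_y] = R(ρ)·[ψ_x, ψ_y]` rotates into visual-streak ("horizon")
coordinates, with ρ a once-per-session annotation; φ is reported relative
to the session-mean eye position.  The pupil centre comes from a direct
least-squares conic fit (centre of `ax²+bxy+cy²+dx+ey=1`) — only the centre
is needed, and on near-elliptical outlines this matches a full ellipse fit
(unit-tested against `skimage.measure.EllipseModel`).  The viewing angle is
the linear sum θ + φ_x.  Speeds (head: rostral point; eye: pupil-outline
centroid, which equals the ellipse centre for symmetric outlines) are mean
frame-to-frame displacement rates over 80–480 ms post-onset.

First-view flags are computed over all trials (the first valid trial is
flagged by convention), but group statistics use standard-condition trials
excluding the first ten: the First10 trials are unadapted by construction
and cluster at one head angle early in the session, so leaving them in
would masquerade as an angle or first-view effect.  The same exclusion
applies to the Left/Right groups.

## Movement-versus-stimulus comparison

Movement onsets are `find_peaks` maxima of the speed trace above
mean + 2 SD with ≥ 1 s separation (thresholds configurable; the defaults
select isolated, unambiguous movements), discarding peaks 80–480 ms after
any stimulus onset or offset.  Each movement epoch's *activity magnitude*
is the maximum over 200 ms windows slid in 50 ms steps across 1 s (head)
or 0.5 s (eye) after onset — 17 or 7 candidate windows, earliest window on
ties — minus the same sliding maximum on the nearest quiet episode (no
movement peak, no stimulus), searched outward in 50 ms steps alternating
before/after with the nearer side first, up to a 30 s horizon.  Stimulus
events use the fixed 80–280 ms post-onset window minus the 200 ms
pre-onset baseline.  Per session, the mean movement magnitude is
subtracted from the mean standard and deviant stimulus magnitudes; a
one-sample, one-sided t test asks whether those differences exceed zero
across sessions (a zero-variance difference vector is reported with a
degenerate-variance flag rather than an exception).

## The synthetic generator

`generate_oddball_session` emulates the four recorded streams.  What it
models, and the values chosen where the protocol fixes none:

* **Evoked response**: a damped 20 Hz sinusoid (decay 150 ms) starting
  80 ms after onset — an oscillatory early response followed by decay.
  Amplitude is 140 µV per unit gain.
* **Gain structure**: deviant trials carry `gain_deviant` (default 3);
  standards decay from `gain_standard_initial` (3) to a floor (1) as
  `floor + (initial − floor)·exp(−k/τ)` with k the count of prior
  presentations at the adaptation key and τ = 4 trials.  τ = 4 makes the
  adaptation transient die within the first ten trials, consistent with
  excluding exactly those trials as the unadapted group.  In
  `adaptation_mode="allocentric"` (default) the key is the screen
  position; in `"retinotopic"` it also includes the 15°-binned true head
  angle at onset, so a never-before-seen viewing angle resets adaptation —
  the contrast the first-view analysis must detect.  Per-trial lognormal
  gain jitter (σ = 0.15, truncated at ±2σ) models response variability.
* **Noise**: 70 µV total, half white and half 1/f, with the 1/f component
  rolled off below 1 Hz as an AC-coupled acquisition chain would.  Without
  that high-pass, session-scale drift dominates the across-trial
  covariance and PC1 locks onto drift instead of the response — a failure
  mode no real AC-coupled recording exhibits.
* **Free-parameter feasibility**: amplitude, noise and jitter jointly
  satisfy two constraints — a gain-4 response peak stays below the 900 µV
  artifact cut (so artifact screening never eats deviant trials, matching
  a design in which all 20 deviants survive screening), and at gain
  ratio 2 the evoked component still dominates the balanced 40×200 sample
  covariance, whose top noise eigenvalue is ~2.3× the per-direction noise
  SD (high-dimensional sample-eigenvalue inflation).
* **Head kinematics**: a mean-reverting (OU) angle walk, 0.8°/frame
  innovations at 15 Hz with a 150 s reversion time, reflected into ±60° —
  the head wanders over minutes and is frozen during a configurable 30% of
  trials.  Head keypoints are the two ends of a 60 px segment through a
  slowly translating centre; injected movement epochs translate the centre
  at 150 px/s for 400 ms inside quiet inter-stimulus intervals.
* **Eye stream**: true angles ψ* follow a bounded walk around 90°; pupil
  keypoints are 8 points on an ellipse around the centre implied by the
  forward arccos model (so the analysis inverts the generator exactly on
  noiseless input), plus occasional 20° saccades; the socket annotation is
  12 points on the true circle.  By default the LFP is movement-silent
  (`movement_lfp_gain = 0`).

Everything is a deterministic function of the config seed; with the same
seed the four streams are bit-identical across runs.

What the generator does **not** model: biophysical LFP genesis, retinal or
receptive-field processing, frame drops or synchronisation error, keypoint
identity switches, spiking.  Passing tests therefore show that the
*analysis chain* recovers planted structure of the assumed form at
realistic amplitudes — not that real recordings satisfy those assumptions.

## Spatial-control projection

Uniform-position control sessions (five positions × 20 repeats) are scored
with the oddball session's axis; applying the recorded orientation sign
implements the rule that sessions with a negative raw novelty effect have
all control scores flipped.  Each oddball trial then has the control mean
score at its own screen position subtracted (the symmetric per-position
form of subtracting the control response from the oddball response), and
the deviant test is re-run; sessions whose corrected effect loses
significance are flagged *bias-explained*.  Note the flag's intrinsic
noisiness: the 20-trial control position means carry sampling error about
1.35× the permutation-null scale, which the null does not account for, so
on a truly bias-explained session the flag is correct only ~60–85% of the
time.  The flag is a screening aid, not a calibrated test.

## Problem sizes and defaults used in validation

Simulation studies (tests, `scripts/acceptance.py`, examples) synthesise
LFP at 2 kHz — any multiple of 400 Hz produces the identical 200-sample
windows, and the window-arithmetic check runs at the full 20 kHz — with
the default 200-trial schedule.  The calibration run uses 400 null
sessions, the power run 100 sessions per gain ratio, the regime comparison
12 sessions per adaptation mode, and the movement comparison 6 sessions.

## Known limitations

* The trial-shuffle p is mildly anti-conservative (see above); the
  across-session tests do not share this issue (session labels are not
  used in any per-session fit).
* The bias-explained flag is stochastic at realistic noise.
* First-view groups are small (~5–15 trials) under a slow head walk, so
  per-session first-view tests have moderate power; regime discrimination
  is reliable in aggregate, not in every single session.
* The offset-response variant reuses the 80–580 ms window measured from
  stimulus offset; no separate offset window is defined.
* Head-angle zeroing uses the circular mean, so sessions with angle
  distributions wider than ±90° would need the reflection bound raised.
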