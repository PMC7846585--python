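# Methods

This note documents the models, conventions and numerical choices
behind `behavloop`, in the order a session flows through the package.

## Coordinate and angle conventions

All coordinates are raster (image) coordinates: origin top-left, x
rightward, y downward, units of pixels. Angles are reported in the
mathematical convention on the y-flipped plane — counterclockwise
positive, degrees, wrapped to the half-open interval (−180, 180] — so a
heading of +90° points *up* in the image. This keeps score-map indexing
and angle arithmetic simultaneously standard. The head-direction angle
α is `wrap(heading − bearing)` where heading is the angle of the
neck→nose vector and bearing the angle of the neck→reference vector;
symmetric windows use only |α|.

## The synthetic animal

The simulator emulates a freely moving mouse for the sole purpose of
driving the engine and its validation statistics; it makes no claim of
behavioral realism beyond what the protocols need.

* **Heading** performs a circular random walk: wrapped Gaussian
  increments with standard deviation `heading_sd` (default 5°/frame at
  30 fps). During a configured bias episode the increment mean is
  `gain · wrap(target_bearing − heading)`, pulling the heading toward a
  bearing; `gain ∈ [0, 1]`.
* **Position** (the neck / body center) takes a half-normal step
  `|N(0, step_sd)|` along the current heading plus isotropic
  `N(0, step_sd/2)` jitter per axis, and is reflected at the arena
  boundary. The half-normal keeps net motion forward along the heading;
  the jitter adds the sideways drift real tracking shows. Steps that
  would leave the arena reflect off the boundary (radially for disks,
  per-axis triangle-wave for rectangles); the boundary is shrunk by
  `max(nose_offset, tail_offset)` so every body part stays inside.
* **Body geometry**: nose and tail root sit on the heading axis at
  +15 px and −30 px from the neck (a ~45 px nose-to-tail-root body,
  matching a ~60 px mouse in 848×480 px recordings). Defaults are
  overridable.
* **Score maps**: per part, a Gaussian bump `exp(−d²/2σ²)` of amplitude
  1 at the true coordinate (σ = `bump_sd` px) plus i.i.d. `N(0,
  noise_sd)` pixel noise, clipped to [0, 1] — the shape a pose network's
  confidence raster takes near a confident detection.

Everything is driven by `numpy.random.default_rng(seed)`; identical
(arena, parameters, seed) give bitwise-identical tracks and maps.

What the simulator does **not** emulate: occlusion, identity swaps,
motion blur, network-specific error structure (heavy-tailed misses,
part confusion), multi-animal scenes, or 3-D posture. Tests passing on
synthetic sessions therefore demonstrate the correctness of the engine,
geometry and statistics — not the accuracy of any particular pose
network on real video.

## Posture detection

Peaks are strict 8-neighborhood local maxima at or above a score
threshold (default 0.1; raise it toward 0.5 when maps carry dense
noise, since spurious noise maxima then disappear while real bumps
survive). A cell equal to a neighbor is not a strict maximum; a plateau
that dominates its surroundings is reported once at its
lexicographically smallest (row, col) cell — a determinism choice.
Peak coordinates are integer cells (no sub-pixel refinement), so a
perfect detector shows a ≤ 0.5 px quantization floor against sub-pixel
truth.

Assembly selects at most one candidate peak per part. With a previous
posture it minimizes the total Euclidean displacement over all
combinations; because candidates are listed per part this decomposes
into independent per-part nearest-candidate choices, which is how it is
computed (the test suite verifies equivalence against brute-force
enumeration). Without a previous posture the highest-score candidate
wins. Ties resolve to the earliest peak in the score-sorted candidate
list. Parts with no candidate are flagged missing, carry the previous
coordinate forward (confidence 0), and block any trigger that requires
them — a conservative false-positive control.

## Triggers and timers

All boundary decisions are closed: |α| exactly W/2 fires, a part
exactly on an ROI rim is inside, a heading exactly perpendicular to the
screen direction still counts as facing. Angular comparisons carry a
1e-9° slack so exact-boundary frames decide deterministically under
floating point.

Timers compare timestamps on the simulated clock `t = frame_id / fps`
and expire at `t − start ≥ duration` (closed), with a 1e-9 s slack;
without it, frame timestamps `k/fps` can miss a 1/5/15 s boundary by
one ulp and stretch an event by a frame.

ROI membership uses the nose for odor/contact triggers and the neck for
proximity, reflecting the distinction between direct contact and being
near a location; both are per-protocol configuration.

## Protocols

* **Head-direction optogenetics** (defaults: 60° window, 1 s minimum,
  5 s maximum, 15 s inter-stimulus, 30-min session): stimulation starts
  on a fired trigger with the gate idle or expired; it continues to the
  minimum duration even if the head leaves the window earlier (the
  animal "could sweep its head away" mid-stimulus), extends while the
  trigger holds, and ends at the first frame where the head is out and
  the minimum has elapsed, or the maximum has elapsed. The gate is
  anchored at stimulation *offset*. A configurable actuator delay
  (frames, default 0) separates the causing frame from the logged
  physical onset, emulating measured hardware latency; the latency
  analysis reads it back from the event log.
* **Conditioning** (20 s trials, 30 s inter-trial interval, 10 s visual
  stimulus, 7 s collection window, caps at 1 h / 40 trials / 20
  collected rewards): a trial starts when the animal faces the screen
  (180° window around the direction toward the screen wall) outside a
  trial and ITI. Trial types are a seeded Bernoulli sequence
  (configurable proportion, default 0.5). The reward is delivered at
  visual-stimulus end and withdrawn 7 s later if the reward ROI was
  not entered; the collection clock starts at delivery. The negative
  trial's tone is delivered at stimulus end, parallel to reward
  delivery (its timing is otherwise unconstrained). When several end
  conditions co-fire on one frame the precedence is success cap >
  trial cap > duration cap, and the binding reason is logged.
* **Second-order conditioning** (quota 10 explorations per odor, 10-min
  cap): an exploration is an outside-to-inside transition of the odor
  trigger — direct contact (nose in ROI) in stage 1, proximity + facing
  in stage 2. Each exploration displays the paired conditioned stimulus
  for 5 s (display length is a package choice); explorations during an
  ongoing display still count.
* **Preference**: passive; investigation time is scored offline as
  nose-in-ROI frames / fps, with sessions investigating no odor flagged
  for exclusion. The paired one-tailed t-test is provided as a
  convenience reporting statistic via scipy.
* **Yoked replay**: the source log's (onset, offset) times are replayed
  verbatim on the subject's own clock; posture input is logged but
  never consulted.

## Session tables

Comma-separated, UTF-8, '\n', floats at six decimals; columns
`frame_id, t, <part>_x, <part>_y, <part>_conf …, experiment_status,
trial, time`. `experiment_status` is true while any output channel
(laser, stimulus display) is active, which makes the event list exactly
recoverable from status transitions; trial identity lives in the
`trial` column. `time` holds the per-frame interval (the simulated
inference time). Confidence 0 is reserved for missing (carried-forward)
parts. A `#`-prefixed header carries protocol, seed and a config hash;
a JSON sidecar stores the full config, events, actions and counters and
is cross-checked against the status-derived events on read.

## Validation statistics

* **Mean resultant length**: `r = |Σ(cos θ, sin θ)|/n`, with the mean
  angle from the atan2 of the sum. For a uniform arc of full width W,
  `r = sin(W/2)/(W/2)` — the closed form the tests recover at n = 10⁵.
* **Permutation null**: equal-size sets are drawn *without replacement*
  from the session's frame-angle multiset (mirroring a subsample of
  actual frames; with/without replacement is otherwise arbitrary),
  1000 times by default. The empirical p uses the add-one correction
  `p = (1 + #{null ≥ observed}) / (1 + N)`; the cutoff is the 99th
  percentile (numpy linear interpolation). The stimulated-angle set is
  all frames with stimulation active, not onset frames only.
* **Trigger accuracy**: for each window width in {60, 50, 40, 30, 20,
  10}° the window `[j·w, (j+1)·w)` is placed at `n_rotations`
  consecutive rotations (default 3, e.g. 0–60°, 60–120°, 120–180°) to
  counter non-uniform head-direction occupancy. Rates are per-frame:
  FP = #{estimated in ∧ true out}/#{estimated in}, FN = #{true in ∧
  estimated out}/#{true in}, reported as mean ± SD over rotations.
* **Latency**: physical onset frame minus causing frame per event,
  overall and per channel.

## Problem sizes and tolerances

The validation analyses run at the printed session scale — 30-minute,
30 fps sessions (54,000 frames) with 1000 resamples. Repetition-heavy
properties (e.g. the expectation that p falls as the stimulated-angle
count grows) use reduced resample counts and repetitions in the test
suite; these sizes are the package's own choices and are stated in the
tests that use them. Closed-form recoveries are asserted to 0.01;
geometric identities to 1e-7–1e-9 degrees; timing contracts to the
1e-9 s timer slack.

## Known limitations

* The closest-distance assembly degrades when candidate peaks are dense
  (heavy map noise at a low threshold): a spurious peak near the
  previous location can outcompete the true one. This is inherent to
  the rule, not the implementation; raising the detection threshold
  suppresses it.
* The engine is single-animal and 2-D; status columns assume output
  channels do not overlap in time within one protocol (true of all
  shipped protocols).
* The simulator's kinematics are an artifact choice — no published
  statistical model of mouse kinematics is implied — so absolute
  event counts/rates from simulated sessions characterize the engine,
  not mice.
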