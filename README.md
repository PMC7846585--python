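# behavloop

Closed-loop, posture-triggered behavioral experiments — hardware-free,
simulated, and testable end to end.

Closed-loop behavioral neuroscience couples stimulus delivery (laser,
reward, tone, screen) to an animal's ongoing behavior, detected in real
time from markerless pose estimation. The engines that do this in the
lab are wired to cameras, DAQ boards and lasers, which makes their
*logic* — trigger geometry, gate timers, trial state machines, session
bookkeeping — hard to test, and their validation statistics hard to
reproduce. `behavloop` re-creates that whole loop on a synthetic
animal, so every protocol rule and every validation statistic can be
exercised, seeded, and checked against ground truth.

It is written for behavioral/systems neuroscientists and research
software engineers who want to prototype or verify closed-loop protocol
logic before (or instead of) touching hardware.

## What's inside

* **Synthetic sessions** (`behavloop.synthetic`) — a freely moving
  mouse in a circular or rectangular arena: bounded positional random
  walk, circular random walk of heading (wrapped Gaussian increments),
  three body parts (nose, neck, tail root), and optional per-part score
  maps (unit Gaussian bumps plus clipped noise) standing in for a pose
  network's confidence rasters. Fully seeded and ground-truthed.
* **Posture detection** (`behavloop.detection`) — strict 8-neighborhood
  local-maxima peak extraction and closest-distance assembly of
  candidate peaks into postures, plus pose-error scoring against the
  ground truth.
* **Triggers** (`behavloop.triggers`) — head-direction window, circular
  ROI, proximity + facing, screen-facing, speed.
* **Experiment engine** (`behavloop.engine`) — frame-by-frame protocol
  state machines: head-direction optogenetics, conditioning,
  second-order conditioning, preference logging, and yoked replay of a
  recorded stimulation timeline.
* **Session I/O** (`behavloop.session_io`) — the frame-indexed,
  comma-separated session table (body-part coordinates, experiment
  status, trial label, per-frame time) with bit-stable round trips.
* **Analysis** (`behavloop.analysis`) — circular statistics with a
  permutation null, radial histograms, trigger FP/FN accuracy over
  window widths, stimulation-latency accounting, investigation-time
  scoring.

## The core statistic

The head-direction angle α is the signed angle between the animal's
heading vector (neck → nose) and the bearing from the neck to a fixed
reference point; the trigger fires while |α| ≤ W/2 for a full window
width W (60° by default). Stimulation holds ≥ 1 s, extends while the
head stays in the window up to 5 s, and is followed by a ≥ 15 s
inter-stimulus gate.

Whether stimulation truly tracked the window is tested with the mean
resultant vector length of the n stimulated angles θⱼ,

    r = (1/n) · | Σⱼ (cos θⱼ, sin θⱼ) |,   0 ≤ r ≤ 1,

(0 = uniform, 1 = point mass). The null hypothesis — the concentration
merely reflects where the animal liked to face — is simulated by
drawing 1000 equal-size angle sets from the full session's angles and
recomputing r each time; the observed r is compared against the 99th
percentile of that null, with an add-one empirical p.

## Worked example

`examples/02_head_direction_session.py` simulates a 30-minute session
(30 fps, 54,000 frames) and runs the head-direction protocol:

```
41 stimulation events, total 66.3 s of light
event durations 1.00 - 5.00 s (protocol bounds: 1 and 5 s)
minimum inter-stimulus gap 15.00 s (gate: 15 s)
stimulated-angle r = 0.910 over 1990 frames
99% null cutoff    = 0.309, p = 0.0010
```

Every event respects the 1–5 s duration bounds and the 15 s gate, and
the stimulated angles are concentrated (r = 0.91) far beyond anything
equal-size random draws from the session achieve (cutoff 0.31) — the
closed loop hit its window, it did not ride a behavioral bias. The
other examples cover detection from score maps, the conditioning and
second-order tasks, and yoked replay.

A thin CLI wraps the same library:

```
behavloop simulate --seed 3 --duration 60 --out truth.csv
behavloop run --config cfg.yaml --seed 5 --out-dir out/
behavloop replay-yoked --source out/session.csv --seed 9 --out-dir out/
behavloop analyze --table out/session.csv --out results.json
```

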