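"""Simulate a moving mouse, render score maps, and recover its posture.

Builds one minute of random-walk kinematics in a circular arena,
renders noisy per-part score maps for a handful of frames, runs
local-maxima detection plus closest-distance assembly, and reports the
pose error against the ground truth.
"""

import numpy as np

from behavloop import (
    ArenaSpec,
    KinematicsParams,
    assemble_posture,
    pose_error,
    render_score_maps,
    simulate_trajectory,
)
from behavloop.detection import detect_stack

arena = ArenaSpec("circle", 200.0, center=(424.0, 240.0),
                  reference_point=(724.0, 240.0), fps=30.0)
track = simulate_trajectory(arena, KinematicsParams(seed=42), 60.0)
print(f"simulated {track.n_frames} frames at {arena.fps:g} fps")

# Detect postures on the first 60 frames from noisy 848x480 score maps.
estimated = []
previous = None
for i in range(60):
    stack = render_score_maps(track.frame(i), 480, 848, bump_sd=3.0,
                              noise_sd=0.05, seed=1000 + i)
    # threshold 0.5: spurious noise maxima (noise_sd 0.05) never reach it,
    # so assembly picks among real candidate bumps only
    posture = assemble_posture(detect_stack(stack, threshold=0.5), previous,
                               frame_id=i, t=track.t[i])
    estimated.append(posture)
    previous = posture

from behavloop import GroundTruthTrack

truth60 = GroundTruthTrack(
    arena=track.arena, frame_id=track.frame_id[:60], t=track.t[:60],
    x=track.x[:60], y=track.y[:60], heading=track.heading[:60],
    nose_offset=track.nose_offset, tail_offset=track.tail_offset,
)
report = pose_error(estimated, truth60)
for part, (mean, sd) in report.per_part.items():
    print(f"{part:10s} position error {mean:.2f} +/- {sd:.2f} px")
hd_mean, hd_sd = report.head_direction_mean_sd
print(f"head-direction error {hd_mean:.2f} +/- {hd_sd:.2f} deg")
print("(sub-pixel truth vs integer peak cells: errors < 1 px mean the")
print(" detector recovered every body part to the nearest raster cell)")
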