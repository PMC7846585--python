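"""Head-direction gated optogenetic stimulation plus validation.

Runs a 30-minute closed-loop session: light stimulation whenever the
simulated mouse's head direction falls in a 60-degree window around the
reference point (1 s minimum, 5 s maximum, 15 s inter-stimulus gap),
then validates that the stimulated angles are more concentrated than a
1000-resample permutation null built from the whole session.
"""

import numpy as np

from behavloop import (
    ArenaSpec,
    HeadDirectionProtocol,
    HeadDirectionWindow,
    KinematicsParams,
    mean_resultant_length,
    permutation_null,
    run_session,
    simulate_trajectory,
)
from behavloop.analysis import session_angles, stimulated_angles

REF = (724.0, 240.0)
arena = ArenaSpec("circle", 200.0, center=(424.0, 240.0),
                  reference_point=REF, fps=30.0)
track = simulate_trajectory(arena, KinematicsParams(seed=5), 1800.0)
window = HeadDirectionWindow(REF, width=60.0)
log = run_session(HeadDirectionProtocol(window, max_duration=None, seed=5),
                  track.to_postures())

durations = [e.duration for e in log.events]
gaps = [b.onset_t - a.offset_t for a, b in zip(log.events, log.events[1:])]
print(f"{len(log.events)} stimulation events, "
      f"total {sum(durations):.1f} s of light")
print(f"event durations {min(durations):.2f} - {max(durations):.2f} s "
      f"(protocol bounds: 1 and 5 s)")
print(f"minimum inter-stimulus gap {min(gaps):.2f} s (gate: 15 s)")

all_angles = session_angles(log, REF)
stim = stimulated_angles(log, REF)
null = permutation_null(all_angles, stim, n_samples=1000, seed=5)
print(f"stimulated-angle r = {null.observed_r:.3f} over {stim.size} frames")
print(f"99% null cutoff    = {null.cutoff_99:.3f}, p = {null.p:.4f}")
print("(r near 1 with p <= 0.01 means stimulation hit the intended window,")
print(" not a behavioral bias: random equal-size angle sets are far more")
print(" dispersed)")
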