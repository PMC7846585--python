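"""Screen-facing conditioning task with a scripted, partly compliant agent.

The agent always faces the screen between trials, and on ~80% of trials
walks to the reward port 3 seconds after delivery.  Trials last 20 s
(10 s visual stimulus) with a 30 s inter-trial interval; rewards are
withdrawn if not collected within 7 s.
"""

import numpy as np

from behavloop import ConditioningProtocol, ROI, run_session, success_rate
from behavloop.posture import make_posture

rng = np.random.default_rng(11)
reward_roi = ROI("reward", (240.0, 40.0), 30.0)

frames = []
collect = False
for i in range(120_000):
    t = i / 30.0
    phase = t % 50.0  # 20 s trial + 30 s ITI, trials start on schedule
    if phase < 1 / 30.0:
        collect = bool(rng.random() < 0.8)
    near_port = collect and 13.0 <= phase < 17.0
    pos = (240.0, 50.0) if near_port else (240.0, 200.0)
    frames.append(make_posture(i, t, {
        "nose": (pos[0], pos[1] - 15.0),  # pointing at the top-wall screen
        "neck": pos,
        "tail_root": (pos[0], pos[1] + 30.0),
    }))

protocol = ConditioningProtocol(
    toward_screen_deg=90.0, reward_roi=reward_roi,
    max_duration=None, max_successes=None, p_positive=0.5, seed=7,
)
log = run_session(protocol, frames)

c = log.counters
print(f"session ended by {log.end_reason} after {c['trials_completed']} trials")
print(f"positive {c['positive_trials_completed']}, "
      f"negative {c['negative_trials_completed']}, "
      f"rewards collected {c['successes']}")
print(f"success rate {success_rate(log):.2f} "
      "(fraction of positive trials whose reward was collected;")
print(" the learning criterion for stage advancement is > 0.85)")
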