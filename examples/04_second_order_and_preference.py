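"""Second-order conditioning and odor-preference scoring.

A scripted agent alternates between two odor dishes every 10 s; each
direct contact displays the paired conditioned stimulus and counts one
exploration.  The session ends once both odors reach 10 explorations.
A preference session is then scored as seconds of nose time per ROI.
"""

from behavloop import ROI, SecondOrderProtocol, investigation_time, run_session
from behavloop.posture import make_posture

roi_a = ROI("rose", (100.0, 240.0), 20.0)
roi_b = ROI("vanillin", (380.0, 240.0), 20.0)

frames = []
for i in range(600 * 30):
    t = i / 30.0
    cx = 100.0 if int(t // 10.0) % 2 == 0 else 380.0
    frames.append(make_posture(i, t, {
        "nose": (cx, 240.0), "neck": (cx - 15.0, 240.0),
        "tail_root": (cx - 45.0, 240.0),
    }))

protocol = SecondOrderProtocol(
    {"rose": roi_a, "vanillin": roi_b},
    {"rose": "cross", "vanillin": "plus"},
    mode="contact", seed=3,
)
log = run_session(protocol, frames)
print(f"session ended by {log.end_reason} at t = {log.records['t'].iloc[-1]:.0f} s")
print(f"explorations: {log.counters['explorations']}")
print(f"stimulus displays: {len(log.events)}")

report = investigation_time(frames[:log.n_frames], [roi_a, roi_b],
                            part="nose", fps=30.0)
for odor, seconds in report.seconds.items():
    print(f"investigation of {odor}: {seconds:.1f} s")
print("(each exploration is one outside-to-inside ROI transition of the")
print(" nose; investigation time is total nose-in-ROI time in seconds)")
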