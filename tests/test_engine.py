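"""Protocol state machines: gating, timers, session ends, yoked replay."""

import numpy as np
import pytest

from behavloop import (
    ConditioningProtocol,
    HeadDirectionProtocol,
    HeadDirectionWindow,
    KinematicsParams,
    PreferenceProtocol,
    ROI,
    SecondOrderProtocol,
    run_session,
    simulate_trajectory,
    success_rate,
    track_from_arrays,
    yoked_from_log,
)
from behavloop.engine import OrderingError, Timer
from behavloop.posture import make_posture

REF = (724.0, 240.0)
WINDOW = HeadDirectionWindow(REF, width=60.0)


def _hd_postures(in_window_mask, fps=30.0):
    """Posture stream whose head is in/out of the target window per frame.

    In-window frames head straight at the reference; out-of-window frames
    head directly away from it.
    """
    out = []
    for i, inside in enumerate(in_window_mask):
        neck = (424.0, 240.0)
        nose = (439.0, 240.0) if inside else (409.0, 240.0)
        out.append(make_posture(i, i / fps, {"neck": neck, "nose": nose}))
    return out


def reference_gating(mask, fps=30.0, min_stim=1.0, max_stim=5.0, gap=15.0):
    """Straight-line re-implementation of the stimulation gating rules.

    Independent oracle: walks the in-window mask and produces
    (onset_t, offset_t) pairs under the minimum/maximum duration and
    inter-stimulus rules, with the gate anchored at stimulation offset.
    """
    eps = 1e-9
    events = []
    on_t = None
    gate_until = -np.inf
    for i, inside in enumerate(mask):
        t = i / fps
        if on_t is not None:
            el = t - on_t
            if el >= max_stim - eps or (not inside and el >= min_stim - eps):
                events.append((on_t, t))
                gate_until = t + gap
                on_t = None
        elif inside and t >= gate_until - eps:
            on_t = t
    if on_t is not None:
        events.append((on_t, (len(mask) - 1) / fps))
    return events


class TestHeadDirectionProtocol:
    def test_continuous_window_gives_max_stim_then_gate(self):
        mask = [True] * (8 * 30)  # 8 s continuously in window
        log = run_session(
            HeadDirectionProtocol(WINDOW, max_duration=None), _hd_postures(mask)
        )
        assert len(log.events) == 1
        assert log.events[0].duration == pytest.approx(5.0)
        assert log.events[0].onset_t == 0.0

    def test_brief_visit_still_gets_min_stim(self):
        mask = [False] * 30 + [True] * 9 + [False] * 120  # 0.3 s visit
        log = run_session(
            HeadDirectionProtocol(WINDOW, max_duration=None), _hd_postures(mask)
        )
        assert len(log.events) == 1
        assert log.events[0].duration == pytest.approx(1.0)

    def test_event_list_matches_reference_simulation(self):
        rng = np.random.default_rng(21)
        # scripted episodes: random visits of 0.1 - 7 s separated by gaps
        mask = []
        while len(mask) < 120 * 30:
            mask += [False] * rng.integers(30, 400)
            mask += [True] * rng.integers(3, 210)
        mask = mask[: 120 * 30]
        log = run_session(
            HeadDirectionProtocol(WINDOW, max_duration=None), _hd_postures(mask)
        )
        got = [(e.onset_t, e.offset_t) for e in log.events]
        assert got == pytest.approx(reference_gating(mask))

    def test_event_invariants_on_random_session(self, circle_arena):
        track = simulate_trajectory(
            circle_arena, KinematicsParams(seed=13), 300.0
        )
        log = run_session(
            HeadDirectionProtocol(WINDOW, max_duration=None),
            track.to_postures(),
        )
        assert log.events, "random walk session should stimulate"
        for ev in log.events:
            assert 1.0 - 1e-9 <= ev.duration <= 5.0 + 1e-9
            assert abs(ev.cause["angle"]) <= 30.0  # fired only inside window
        gaps = [
            b.onset_t - a.offset_t
            for a, b in zip(log.events, log.events[1:])
        ]
        assert all(g >= 15.0 - 1e-9 for g in gaps)
        # no overlap, by construction of the gaps
        assert all(g > 0 for g in gaps)

    def test_seed_determinism(self, circle_arena):
        track = simulate_trajectory(circle_arena, KinematicsParams(seed=3), 60.0)
        a = run_session(HeadDirectionProtocol(WINDOW, seed=5), track.to_postures())
        b = run_session(HeadDirectionProtocol(WINDOW, seed=5), track.to_postures())
        assert a.equals(b)

    def test_actuator_delay_recorded(self):
        mask = [True] * 60
        log = run_session(
            HeadDirectionProtocol(WINDOW, max_duration=None, actuator_delay=5),
            _hd_postures(mask),
        )
        ev = log.events[0]
        assert ev.physical_onset_frame - ev.onset_frame == 5

    def test_ordering_violation_rejected(self):
        from behavloop.posture import Posture

        frames = _hd_postures([True, True])
        frames[1] = Posture(0, 0.0, frames[1].parts)
        with pytest.raises(OrderingError):
            run_session(HeadDirectionProtocol(WINDOW), frames)

    def test_empty_stream_gives_empty_log(self):
        log = run_session(HeadDirectionProtocol(WINDOW), [])
        assert log.n_frames == 0
        assert log.events == []


def _facing_track(arena, n, pos=(240.0, 200.0), facing=True):
    nose_y = pos[1] - 15.0 if facing else pos[1] + 15.0
    return [
        make_posture(i, i / 30.0, {
            "nose": (pos[0], nose_y), "neck": pos,
            "tail_root": (pos[0], pos[1] + 30.0),
        })
        for i in range(n)
    ]


class TestConditioningProtocol:
    REWARD = ROI("reward", (240.0, 40.0), 30.0)

    def _protocol(self, **kw):
        kw.setdefault("max_duration", 3600.0)
        return ConditioningProtocol(90.0, self.REWARD, seed=5, **kw)

    def test_never_facing_agent_ends_at_duration_cap(self):
        frames = _facing_track(None, 40 * 30, facing=False)
        log = run_session(self._protocol(max_duration=30.0), frames)
        assert log.counters["trials_started"] == 0
        assert log.end_reason == "duration_cap"

    def test_compliant_agent_ends_at_success_cap(self):
        # agent sits in the reward ROI while facing the screen: every
        # positive reward is collected instantly
        frames = _facing_track(None, 60000, pos=(240.0, 50.0))
        log = run_session(
            self._protocol(max_duration=None, p_positive=1.0), frames
        )
        assert log.end_reason == "success_cap"
        assert log.counters["successes"] == 20
        assert log.counters["trials_completed"] == 20
        assert success_rate(log) == 1.0

    def test_trial_cap_binds_when_rewards_never_collected(self):
        frames = _facing_track(None, 65000)  # faces screen, far from reward
        log = run_session(
            self._protocol(max_duration=None, max_successes=None), frames
        )
        assert log.end_reason == "trial_cap"
        assert log.counters["trials_started"] == 40
        assert log.counters["successes"] == 0

    def test_reward_collected_within_window_is_success(self):
        # approach the reward ROI 3 s after delivery (t = 13 s in trial 1)
        frames = []
        for i in range(0, 20 * 30):
            t = i / 30.0
            pos = (240.0, 50.0) if t >= 13.0 else (240.0, 200.0)
            frames.append(make_posture(i, t, {
                "nose": (pos[0], pos[1] - 15.0), "neck": pos,
                "tail_root": (pos[0], pos[1] + 30.0),
            }))
        log = run_session(self._protocol(p_positive=1.0), frames)
        names = [a.name for a in log.actions]
        assert "deliver_reward" in names
        assert "reward_collected" in names
        assert "withdraw_reward" not in names

    def test_uncollected_reward_withdrawn_after_seven_seconds(self):
        frames = _facing_track(None, 20 * 30)
        log = run_session(self._protocol(p_positive=1.0), frames)
        deliver = next(a for a in log.actions if a.name == "deliver_reward")
        withdraw = next(a for a in log.actions if a.name == "withdraw_reward")
        assert withdraw.t - deliver.t == pytest.approx(7.0)
        assert deliver.t == pytest.approx(10.0)  # at end of visual stimulus

    def test_negative_trial_plays_tone_without_reward(self):
        frames = _facing_track(None, 20 * 30)
        log = run_session(self._protocol(p_positive=0.0), frames)
        names = [a.name for a in log.actions]
        assert "play_tone" in names
        assert "deliver_reward" not in names

    def test_trial_and_iti_clocks(self):
        frames = _facing_track(None, 110 * 30)
        log = run_session(self._protocol(max_duration=None), frames)
        starts = [a.t for a in log.actions if a.name == "trial_start"]
        assert starts[:3] == pytest.approx([0.0, 50.0, 100.0])  # 20 s + 30 s ITI

    def test_success_rate_matches_recount_from_log(self):
        rng = np.random.default_rng(17)
        frames = []
        collect = True
        for i in range(120000):
            t = i / 30.0
            phase = t % 50.0
            if phase < 1 / 30.0:
                collect = bool(rng.random() < 0.9)
            near = collect and 10.0 <= phase < 17.0
            pos = (240.0, 50.0) if near else (240.0, 200.0)
            frames.append(make_posture(i, t, {
                "nose": (pos[0], pos[1] - 15.0), "neck": pos,
                "tail_root": (pos[0], pos[1] + 30.0),
            }))
        log = run_session(
            self._protocol(max_duration=None, max_successes=None,
                           p_positive=0.5), frames
        )
        assert log.counters["trials_completed"] == 40
        collected = sum(1 for a in log.actions if a.name == "reward_collected")
        positives = log.counters["positive_trials_completed"]
        assert positives > 0
        assert success_rate(log) == pytest.approx(collected / positives)

    def test_success_rate_undefined_without_positive_trials(self):
        frames = _facing_track(None, 30, facing=False)
        log = run_session(self._protocol(max_duration=1.0), frames)
        with pytest.raises(ValueError):
            success_rate(log)


class TestSecondOrderProtocol:
    A = ROI("A", (100.0, 240.0), 20.0)
    B = ROI("B", (380.0, 240.0), 20.0)

    def _alternating(self, n, period=10.0):
        frames = []
        for i in range(n):
            t = i / 30.0
            at_a = int(t // period) % 2 == 0
            pos = (85.0, 240.0) if at_a else (365.0, 240.0)  # nose hits center
            frames.append(make_posture(i, t, {
                "nose": (pos[0] + 15.0, pos[1]), "neck": pos,
                "tail_root": (pos[0] - 30.0, pos[1]),
            }))
        return frames

    def _protocol(self, **kw):
        return SecondOrderProtocol(
            {"A": self.A, "B": self.B}, {"A": "plus", "B": "cross"},
            seed=3, **kw
        )

    def test_alternating_agent_ends_on_exploration_quota(self):
        log = run_session(self._protocol(), self._alternating(18000))
        assert log.end_reason == "exploration_quota"
        assert log.counters["explorations"] == {"A": 10, "B": 10}
        assert log.records["t"].iloc[-1] == pytest.approx(190.0)

    def test_slow_agent_hits_time_cap(self):
        log = run_session(self._protocol(), self._alternating(18500, period=40.0))
        assert log.end_reason == "duration_cap"
        assert log.records["t"].iloc[-1] == pytest.approx(600.0)

    def test_each_exploration_shows_paired_stimulus(self):
        log = run_session(self._protocol(), self._alternating(18000))
        shows = [a for a in log.actions if a.name == "stim_on"]
        assert {a.info["stimulus"] for a in shows} == {"plus", "cross"}
        explorations = [a for a in log.actions if a.name == "exploration"]
        assert len(explorations) == 20


class TestPreferenceProtocol:
    def test_logs_roi_occupancy_without_stimulation(self):
        rois = {"V": ROI("V", (100.0, 100.0), 25.0)}
        frames = [
            make_posture(i, i / 30.0, {"nose": (100.0, 100.0),
                                       "neck": (100.0, 120.0),
                                       "tail_root": (100.0, 150.0)})
            for i in range(60)
        ]
        log = run_session(PreferenceProtocol(rois, max_duration=None), frames)
        assert log.events == []
        assert set(log.records["trial"]) == {"V"}


class TestYokedReplay:
    def test_empty_source_yields_no_events(self, circle_arena):
        empty = run_session(
            HeadDirectionProtocol(WINDOW, max_duration=None), []
        )
        proto = yoked_from_log(empty)
        track = simulate_trajectory(circle_arena, KinematicsParams(seed=2), 10.0)
        log = run_session(proto, track.to_postures())
        assert log.events == []

    def test_timeline_equality_and_posture_independence(self, circle_arena):
        src_track = simulate_trajectory(
            circle_arena, KinematicsParams(seed=42), 120.0
        )
        src = run_session(
            HeadDirectionProtocol(WINDOW, max_duration=None),
            src_track.to_postures(),
        )
        assert src.events
        want = [(e.onset_t, e.offset_t) for e in src.events]
        for seed in (101, 102, 103):  # three independent random tracks
            track = simulate_trajectory(
                circle_arena, KinematicsParams(seed=seed), 120.0
            )
            log = run_session(yoked_from_log(src), track.to_postures())
            got = [(e.onset_t, e.offset_t) for e in log.events]
            assert got == pytest.approx(want)


class TestTimer:
    def test_lifecycle(self):
        timer = Timer(2.0)
        assert timer.status(0.0) == "idle"
        timer.start(1.0)
        assert timer.status(2.9) == "running"
        assert timer.status(3.0) == "expired"  # closed upper bound
        timer.reset()
        assert timer.idle

    def test_rejects_negative_duration(self):
        with pytest.raises(ValueError):
            Timer(-1.0)
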