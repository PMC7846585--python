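"""Frame-by-frame experiment engine.

Protocols wire posture-based triggers through gate timers to
stimulation channels.  Each protocol is a small state machine advanced
one frame at a time by :func:`run_session`; it emits instantaneous
actions (stim_on, show_stimulus, deliver_reward, play_tone, ...) and
maintains interval events (laser on, stimulus displayed) on named
output channels.  The simulated clock is ``t = frame_id / fps``; all
timers compare timestamps with the expired bound closed
(``t - start >= duration``), using a 1e-9 s slack so frame timestamps
hit second boundaries exactly.

Implemented protocols
---------------------
* :class:`HeadDirectionProtocol` - optogenetic stimulation gated on a
  head-direction target window: stimulation holds for at least
  ``min_stim`` seconds, extends while the head stays in the window up
  to ``max_stim``, and is followed by an ``inter_stimulus`` lockout
  that starts at stimulation offset.
* :class:`ConditioningProtocol` - screen-facing triggered trials with a
  visual stimulus, a reward that is withdrawn if not collected in time
  (positive trials) or an aversive tone (negative trials), inter-trial
  interval, and session-end caps (duration / trial count / success
  count).
* :class:`SecondOrderProtocol` - odor-exploration triggered display of
  previously conditioned stimuli, ending on an exploration quota for
  both odors or a time cap.
* :class:`PreferenceProtocol` - passive ROI logging for offline
  preference scoring.
* :class:`YokedProtocol` - replays another session's stimulation
  timeline, decoupled from the animal's own posture.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import ROI
from .posture import Posture
from .triggers import (
    HeadDirectionWindow,
    head_direction_trigger,
    proximity_facing_trigger,
    region_trigger,
    screen_facing_trigger,
)

__all__ = [
    "EPS",
    "Timer",
    "Action",
    "StimulationEvent",
    "SessionLog",
    "Protocol",
    "HeadDirectionProtocol",
    "ConditioningProtocol",
    "SecondOrderProtocol",
    "PreferenceProtocol",
    "YokedProtocol",
    "run_session",
    "success_rate",
    "yoked_from_log",
    "OrderingError",
]

EPS = 1e-9  # timer slack, seconds


class OrderingError(ValueError):
    """Raised when the posture stream is not strictly frame-ordered."""


class Timer:
    """Elapsed-time gate.

    idle until started; running while ``t - started_at < duration``;
    expired once ``t - started_at >= duration`` (closed upper bound).
    """

    def __init__(self, duration: float):
        if duration < 0:
            raise ValueError("timer duration must be >= 0")
        self.duration = float(duration)
        self.started_at: float | None = None

    def start(self, t: float) -> None:
        self.started_at = float(t)

    def reset(self) -> None:
        self.started_at = None

    @property
    def idle(self) -> bool:
        return self.started_at is None

    def running(self, t: float) -> bool:
        return self.started_at is not None and t - self.started_at < self.duration - EPS

    def expired(self, t: float) -> bool:
        return self.started_at is not None and t - self.started_at >= self.duration - EPS

    def status(self, t: float) -> str:
        if self.idle:
            return "idle"
        return "expired" if self.expired(t) else "running"


@dataclass(frozen=True)
class Action:
    """Instantaneous protocol output tagged with its causing frame."""

    name: str
    frame_id: int
    t: float
    info: Mapping[str, object] = field(default_factory=dict)


@dataclass
class StimulationEvent:
    """One interval on an output channel (laser on, stimulus shown).

    ``onset_frame`` is the causing frame; with a configured actuator
    delay the logged physical onset lags by that many frames,
    emulating hardware latency between detection and device output.
    Frames with ``onset_frame <= f < offset_frame`` count as active.
    """

    channel: str
    onset_frame: int
    onset_t: float
    offset_frame: int | None = None
    offset_t: float | None = None
    cause: Mapping[str, object] = field(default_factory=dict)
    actuator_delay: int = 0

    @property
    def duration(self) -> float:
        if self.offset_t is None:
            raise ValueError("event still open")
        return self.offset_t - self.onset_t

    @property
    def physical_onset_frame(self) -> int:
        return self.onset_frame + self.actuator_delay

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "onset_frame": self.onset_frame,
            "onset_t": self.onset_t,
            "offset_frame": self.offset_frame,
            "offset_t": self.offset_t,
            "cause": dict(self.cause),
            "actuator_delay": self.actuator_delay,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationEvent":
        return cls(
            channel=d["channel"],
            onset_frame=int(d["onset_frame"]),
            onset_t=float(d["onset_t"]),
            offset_frame=None if d["offset_frame"] is None else int(d["offset_frame"]),
            offset_t=None if d["offset_t"] is None else float(d["offset_t"]),
            cause=dict(d.get("cause", {})),
            actuator_delay=int(d.get("actuator_delay", 0)),
        )


@dataclass
class SessionLog:
    """Complete record of one session: per-frame rows, events, actions."""

    protocol: str
    seed: int
    config: dict
    fps: float
    skeleton: tuple[str, ...]
    records: pd.DataFrame
    events: list[StimulationEvent] = field(default_factory=list)
    actions: list[Action] = field(default_factory=list)
    counters: dict = field(default_factory=dict)
    end_reason: str = "stream_end"

    @property
    def n_frames(self) -> int:
        return len(self.records)

    def events_on(self, channel: str) -> list[StimulationEvent]:
        return [e for e in self.events if e.channel == channel]

    def equals(self, other: "SessionLog", tol: float = 5e-7) -> bool:
        if (
            self.protocol != other.protocol
            or self.seed != other.seed
            or self.fps != other.fps
            or tuple(self.skeleton) != tuple(other.skeleton)
            or self.end_reason != other.end_reason
            or len(self.events) != len(other.events)
            or len(self.records) != len(other.records)
        ):
            return False
        for a, b in zip(self.events, other.events):
            if a.channel != b.channel or a.onset_frame != b.onset_frame:
                return False
            if a.offset_frame != b.offset_frame or a.actuator_delay != b.actuator_delay:
                return False
        if len(self.records):
            num = self.records.select_dtypes(include=[np.number])
            onum = other.records[num.columns]
            if not np.allclose(num.to_numpy(float), onum.to_numpy(float),
                               atol=tol, equal_nan=True):
                return False
            for col in ("experiment_status", "trial"):
                if not (self.records[col].fillna("").astype(str)
                        == other.records[col].fillna("").astype(str)).all():
                    return False
        return True


class Protocol:
    """Base protocol: channel/event bookkeeping and end-of-session state."""

    name = "base"

    def __init__(self, *, fps: float = 30.0, seed: int = 0, actuator_delay: int = 0):
        if fps <= 0:
            raise ValueError("fps must be > 0")
        self.fps = float(fps)
        self.seed = int(seed)
        self.actuator_delay = int(actuator_delay)
        self.reset()

    # -- lifecycle -------------------------------------------------------

    def reset(self) -> None:
        self.rng = np.random.default_rng(self.seed)
        self.events: list[StimulationEvent] = []
        self._open: dict[str, StimulationEvent] = {}
        self._ended = False
        self.end_reason: str | None = None
        self.trial_label = ""
        self.counters: dict = {}

    def step(self, posture: Posture) -> list[Action]:  # pragma: no cover
        raise NotImplementedError

    def finalize(self, frame_id: int, t: float) -> list[Action]:
        """Close any open channel events at the end of the stream."""
        actions = []
        for channel in list(self._open):
            actions.append(self._close_event(channel, frame_id, t))
        return actions

    def config(self) -> dict:
        return {"fps": self.fps, "seed": self.seed,
                "actuator_delay": self.actuator_delay}

    # -- channel events --------------------------------------------------

    @property
    def status(self) -> bool:
        """True while any output channel is active (this frame)."""
        return bool(self._open)

    def _open_event(self, channel: str, posture: Posture, cause: Mapping) -> Action:
        if channel in self._open:
            raise RuntimeError(f"channel {channel!r} already active")
        ev = StimulationEvent(
            channel=channel,
            onset_frame=posture.frame_id,
            onset_t=posture.t,
            cause=dict(cause),
            actuator_delay=self.actuator_delay,
        )
        self._open[channel] = ev
        self.events.append(ev)
        return Action("stim_on", posture.frame_id, posture.t,
                      {"channel": channel, **cause})

    def _close_event(self, channel: str, frame_id: int, t: float) -> Action:
        ev = self._open.pop(channel)
        ev.offset_frame = int(frame_id)
        ev.offset_t = float(t)
        return Action("stim_off", frame_id, t, {"channel": channel})

    def _end(self, posture: Posture, reason: str) -> Action:
        self._ended = True
        self.end_reason = reason
        return Action("end_session", posture.frame_id, posture.t, {"reason": reason})


class HeadDirectionProtocol(Protocol):
    """Optogenetic stimulation gated on a head-direction target window.

    Stimulation starts when the head-direction angle to the reference
    point enters the (full-width) target window and the inter-stimulus
    gate is not running.  It lasts at least ``min_stim`` seconds (even
    if the head leaves the window earlier), extends while the head
    stays in the window, and stops at ``max_stim`` seconds at the
    latest.  The inter-stimulus gate starts at stimulation *offset*.
    """

    name = "head_direction_optogenetics"
    channel = "laser"

    def __init__(
        self,
        window: HeadDirectionWindow,
        *,
        min_stim: float = 1.0,
        max_stim: float = 5.0,
        inter_stimulus: float = 15.0,
        max_duration: float | None = 1800.0,
        fps: float = 30.0,
        seed: int = 0,
        actuator_delay: int = 0,
    ):
        if min_stim > max_stim:
            raise ValueError("min_stim must be <= max_stim")
        self.window = window
        self.min_stim = float(min_stim)
        self.max_stim = float(max_stim)
        self.inter_stimulus = float(inter_stimulus)
        self.max_duration = max_duration
        super().__init__(fps=fps, seed=seed, actuator_delay=actuator_delay)

    def reset(self) -> None:
        super().reset()
        self.gate = Timer(self.inter_stimulus)
        self.counters = {"stimulations": 0}

    def step(self, posture: Posture) -> list[Action]:
        t = posture.t
        actions: list[Action] = []
        res = head_direction_trigger(posture, self.window)
        if self.channel in self._open:
            ev = self._open[self.channel]
            elapsed = t - ev.onset_t
            stop = elapsed >= self.max_stim - EPS or (
                not res.fired and elapsed >= self.min_stim - EPS
            )
            if stop:
                actions.append(self._close_event(self.channel, posture.frame_id, t))
                self.gate.start(t)
        elif res.fired and (self.gate.idle or self.gate.expired(t)):
            actions.append(self._open_event(self.channel, posture, res.payload))
            self.counters["stimulations"] += 1
        self.trial_label = "stim" if self.channel in self._open else ""
        if (
            not self._ended
            and self.max_duration is not None
            and t >= self.max_duration - EPS
        ):
            actions.append(self._end(posture, "duration_cap"))
        return actions

    def config(self) -> dict:
        return {
            **super().config(),
            "protocol": self.name,
            "window": {
                "reference_point": list(self.window.reference_point),
                "width": self.window.width,
                "axis": list(self.window.axis),
            },
            "min_stim": self.min_stim,
            "max_stim": self.max_stim,
            "inter_stimulus": self.inter_stimulus,
            "max_duration": self.max_duration,
        }


class ConditioningProtocol(Protocol):
    """Screen-facing triggered conditioning with reward/tone outcomes.

    A trial starts when the animal faces the screen (heading within a
    symmetric window around the direction toward the screen wall) and
    no trial or inter-trial interval is pending.  The visual stimulus
    is displayed for ``stimulus_s`` seconds from trial start; at
    stimulus end a positive trial delivers a reward that is withdrawn
    if the reward ROI is not entered within ``collect_s`` seconds,
    while a negative trial plays the aversive tone.  Trial types are a
    seeded random sequence.  The session ends at the earliest of the
    success cap, the trial cap and the duration cap (that precedence
    when several bind on one frame).
    """

    name = "conditioning"
    channel = "screen"

    def __init__(
        self,
        toward_screen_deg: float,
        reward_roi: ROI,
        *,
        facing_width: float = 180.0,
        reward_part: str = "nose",
        trial_s: float = 20.0,
        iti_s: float = 30.0,
        stimulus_s: float = 10.0,
        collect_s: float = 7.0,
        max_duration: float | None = 3600.0,
        max_trials: int | None = 40,
        max_successes: int | None = 20,
        p_positive: float = 0.5,
        fps: float = 30.0,
        seed: int = 0,
        actuator_delay: int = 0,
    ):
        self.toward_screen_deg = float(toward_screen_deg)
        self.reward_roi = reward_roi
        self.facing_width = float(facing_width)
        self.reward_part = reward_part
        self.trial_s = float(trial_s)
        self.iti_s = float(iti_s)
        self.stimulus_s = float(stimulus_s)
        self.collect_s = float(collect_s)
        self.max_duration = max_duration
        self.max_trials = max_trials
        self.max_successes = max_successes
        self.p_positive = float(p_positive)
        super().__init__(fps=fps, seed=seed, actuator_delay=actuator_delay)

    def reset(self) -> None:
        super().reset()
        self.iti = Timer(self.iti_s)
        self.in_trial = False
        self.trial_positive = False
        self.trial_start_t = 0.0
        self.reward_pending = False
        self.reward_delivered_t = 0.0
        self.collected = False
        self.counters = {
            "trials_started": 0,
            "trials_completed": 0,
            "positive_trials_completed": 0,
            "negative_trials_completed": 0,
            "successes": 0,
        }

    def step(self, posture: Posture) -> list[Action]:
        t = posture.t
        fid = posture.frame_id
        actions: list[Action] = []
        c = self.counters
        if self.in_trial:
            elapsed = t - self.trial_start_t
            if self.channel in self._open and elapsed >= self.stimulus_s - EPS:
                actions.append(self._close_event(self.channel, fid, t))
                if self.trial_positive:
                    self.reward_pending = True
                    self.reward_delivered_t = t
                    actions.append(Action("deliver_reward", fid, t,
                                          {"trial": c["trials_started"]}))
                else:
                    actions.append(Action("play_tone", fid, t,
                                          {"trial": c["trials_started"]}))
            if self.reward_pending:
                res = region_trigger(posture, self.reward_roi, part=self.reward_part)
                if res.fired:
                    self.reward_pending = False
                    self.collected = True
                    c["successes"] += 1
                    actions.append(Action("reward_collected", fid, t,
                                          {"trial": c["trials_started"]}))
                elif t - self.reward_delivered_t >= self.collect_s - EPS:
                    self.reward_pending = False
                    actions.append(Action("withdraw_reward", fid, t,
                                          {"trial": c["trials_started"]}))
            if elapsed >= self.trial_s - EPS:
                self.in_trial = False
                self.trial_label = ""
                c["trials_completed"] += 1
                if self.trial_positive:
                    c["positive_trials_completed"] += 1
                else:
                    c["negative_trials_completed"] += 1
                self.iti.start(t)
                actions.append(Action("trial_end", fid, t, {
                    "trial": c["trials_started"],
                    "success": self.collected and self.trial_positive,
                }))
                if (
                    self.max_successes is not None
                    and c["successes"] >= self.max_successes
                ):
                    actions.append(self._end(posture, "success_cap"))
                elif (
                    self.max_trials is not None
                    and c["trials_completed"] >= self.max_trials
                ):
                    actions.append(self._end(posture, "trial_cap"))
        elif self.iti.idle or self.iti.expired(t):
            res = screen_facing_trigger(
                posture, self.toward_screen_deg, width=self.facing_width
            )
            if res.fired:
                self.in_trial = True
                self.trial_start_t = t
                self.trial_positive = bool(self.rng.random() < self.p_positive)
                self.reward_pending = False
                self.collected = False
                c["trials_started"] += 1
                kind = "P" if self.trial_positive else "N"
                self.trial_label = f"{kind}{c['trials_started']}"
                actions.append(Action("trial_start", fid, t, {
                    "trial": c["trials_started"], "positive": self.trial_positive,
                }))
                actions.append(self._open_event(self.channel, posture, {
                    "stimulus": "positive" if self.trial_positive else "negative",
                    **res.payload,
                }))
        if (
            not self._ended
            and self.max_duration is not None
            and t >= self.max_duration - EPS
        ):
            actions.append(self._end(posture, "duration_cap"))
        return actions

    def config(self) -> dict:
        return {
            **super().config(),
            "protocol": self.name,
            "toward_screen_deg": self.toward_screen_deg,
            "facing_width": self.facing_width,
            "reward_roi": {"id": self.reward_roi.id,
                           "center": list(self.reward_roi.center),
                           "radius": self.reward_roi.radius},
            "reward_part": self.reward_part,
            "trial_s": self.trial_s,
            "iti_s": self.iti_s,
            "stimulus_s": self.stimulus_s,
            "collect_s": self.collect_s,
            "max_duration": self.max_duration,
            "max_trials": self.max_trials,
            "max_successes": self.max_successes,
            "p_positive": self.p_positive,
        }


class SecondOrderProtocol(Protocol):
    """Odor-exploration triggered display of conditioned stimuli.

    Stage 1 counts direct contact (nose inside the odor ROI); stage 2
    counts proximity (neck within a radius of the odor location) plus
    facing.  Each new exploration (an outside-to-inside transition of
    the trigger) increments that odor's counter and displays the paired
    stimulus for ``stimulus_s`` seconds.  The session ends when every
    odor's counter reaches ``quota``, or at the duration cap.
    """

    name = "second_order"
    channel = "screen"

    def __init__(
        self,
        odor_rois: Mapping[str, ROI],
        stimulus_map: Mapping[str, str],
        *,
        mode: str = "contact",
        contact_part: str = "nose",
        proximity_radius: float = 60.0,
        facing_width: float = 60.0,
        stimulus_s: float = 5.0,
        quota: int = 10,
        max_duration: float | None = 600.0,
        fps: float = 30.0,
        seed: int = 0,
        actuator_delay: int = 0,
    ):
        if mode not in ("contact", "proximity_facing"):
            raise ValueError("mode must be 'contact' or 'proximity_facing'")
        if set(stimulus_map) != set(odor_rois):
            raise ValueError("stimulus_map must cover exactly the odor ROIs")
        self.odor_rois = dict(odor_rois)
        self.stimulus_map = dict(stimulus_map)
        self.mode = mode
        self.contact_part = contact_part
        self.proximity_radius = float(proximity_radius)
        self.facing_width = float(facing_width)
        self.stimulus_s = float(stimulus_s)
        self.quota = int(quota)
        self.max_duration = max_duration
        super().__init__(fps=fps, seed=seed, actuator_delay=actuator_delay)

    def reset(self) -> None:
        super().reset()
        self.inside = {odor: False for odor in self.odor_rois}
        self.stim_until: float | None = None
        self.counters = {"explorations": {odor: 0 for odor in self.odor_rois}}

    def _odor_trigger(self, posture: Posture, odor: str):
        roi = self.odor_rois[odor]
        if self.mode == "contact":
            return region_trigger(posture, roi, part=self.contact_part)
        return proximity_facing_trigger(
            posture, roi.center, self.proximity_radius, self.facing_width
        )

    def step(self, posture: Posture) -> list[Action]:
        t = posture.t
        fid = posture.frame_id
        actions: list[Action] = []
        if self.channel in self._open and t >= self.stim_until - EPS:
            actions.append(self._close_event(self.channel, fid, t))
            self.stim_until = None
        explored = self.counters["explorations"]
        for odor in self.odor_rois:
            res = self._odor_trigger(posture, odor)
            entering = res.fired and not self.inside[odor]
            self.inside[odor] = res.fired
            if entering:
                explored[odor] += 1
                actions.append(Action("exploration", fid, t, {
                    "odor": odor, "count": explored[odor],
                }))
                if self.channel not in self._open:
                    actions.append(self._open_event(self.channel, posture, {
                        "stimulus": self.stimulus_map[odor], "odor": odor,
                    }))
                    self.stim_until = t + self.stimulus_s
        self.trial_label = ",".join(o for o in self.odor_rois if self.inside[o])
        if not self._ended:
            if all(v >= self.quota for v in explored.values()):
                actions.append(self._end(posture, "exploration_quota"))
            elif self.max_duration is not None and t >= self.max_duration - EPS:
                actions.append(self._end(posture, "duration_cap"))
        return actions

    def config(self) -> dict:
        return {
            **super().config(),
            "protocol": self.name,
            "odor_rois": {o: {"center": list(r.center), "radius": r.radius}
                          for o, r in self.odor_rois.items()},
            "stimulus_map": dict(self.stimulus_map),
            "mode": self.mode,
            "contact_part": self.contact_part,
            "proximity_radius": self.proximity_radius,
            "facing_width": self.facing_width,
            "stimulus_s": self.stimulus_s,
            "quota": self.quota,
            "max_duration": self.max_duration,
        }


class PreferenceProtocol(Protocol):
    """Passive ROI logging for the odor-preference task.

    No stimulation is delivered; the trial column records which odor
    ROI the nose currently occupies so that investigation time can be
    scored offline.
    """

    name = "preference"

    def __init__(
        self,
        odor_rois: Mapping[str, ROI],
        *,
        part: str = "nose",
        max_duration: float | None = 600.0,
        fps: float = 30.0,
        seed: int = 0,
    ):
        self.odor_rois = dict(odor_rois)
        self.part = part
        self.max_duration = max_duration
        super().__init__(fps=fps, seed=seed)

    def step(self, posture: Posture) -> list[Action]:
        t = posture.t
        actions: list[Action] = []
        label = ""
        for odor, roi in self.odor_rois.items():
            if region_trigger(posture, roi, part=self.part).fired:
                label = odor
                break
        self.trial_label = label
        if (
            not self._ended
            and self.max_duration is not None
            and t >= self.max_duration - EPS
        ):
            actions.append(self._end(posture, "duration_cap"))
        return actions

    def config(self) -> dict:
        return {
            **super().config(),
            "protocol": self.name,
            "odor_rois": {o: {"center": list(r.center), "radius": r.radius}
                          for o, r in self.odor_rois.items()},
            "part": self.part,
            "max_duration": self.max_duration,
        }


class YokedProtocol(Protocol):
    """Replay of a source session's stimulation timeline.

    The stimulation onset/offset times are taken verbatim from the
    paired source session; the subject's own posture stream is logged
    but never consulted for stimulation decisions.
    """

    name = "yoked"

    def __init__(
        self,
        timeline: Sequence[tuple[str, float, float]],
        *,
        max_duration: float | None = 1800.0,
        fps: float = 30.0,
        seed: int = 0,
        actuator_delay: int = 0,
    ):
        tl = sorted(
            ((str(c), float(a), float(b)) for c, a, b in timeline),
            key=lambda e: e[1],
        )
        for c, a, b in tl:
            if b < a:
                raise ValueError("timeline offsets must be >= onsets")
        self.timeline = tl
        self.max_duration = max_duration
        super().__init__(fps=fps, seed=seed, actuator_delay=actuator_delay)

    def reset(self) -> None:
        super().reset()
        self._idx = 0
        self._cur_offset: float | None = None
        self._cur_channel: str | None = None
        self.counters = {"stimulations": 0}

    def step(self, posture: Posture) -> list[Action]:
        t = posture.t
        fid = posture.frame_id
        actions: list[Action] = []
        if self._cur_channel is not None and t >= self._cur_offset - EPS:
            actions.append(self._close_event(self._cur_channel, fid, t))
            self._cur_channel = None
            self._cur_offset = None
        if (
            self._cur_channel is None
            and self._idx < len(self.timeline)
            and t >= self.timeline[self._idx][1] - EPS
        ):
            channel, onset, offset = self.timeline[self._idx]
            actions.append(self._open_event(channel, posture,
                                            {"yoked_index": self._idx}))
            self._cur_channel = channel
            self._cur_offset = offset
            self._idx += 1
            self.counters["stimulations"] += 1
        self.trial_label = "stim" if self._cur_channel is not None else ""
        if (
            not self._ended
            and self.max_duration is not None
            and t >= self.max_duration - EPS
        ):
            actions.append(self._end(posture, "duration_cap"))
        return actions

    def config(self) -> dict:
        return {
            **super().config(),
            "protocol": self.name,
            "timeline": [list(e) for e in self.timeline],
            "max_duration": self.max_duration,
        }


def run_session(protocol: Protocol, frames: Iterable[Posture]) -> SessionLog:
    """Run a protocol over an ordered posture stream and collect the log.

    The stream ends at the earliest protocol end condition or when it
    is exhausted; open channel events are closed at the final frame.
    An empty stream yields an empty log with zero events.
    """
    protocol.reset()
    records: list[dict] = []
    actions: list[Action] = []
    skeleton: tuple[str, ...] = ()
    prev_frame: int | None = None
    prev_t: float | None = None
    end_reason: str | None = None
    last: Posture | None = None

    for posture in frames:
        if prev_frame is not None and posture.frame_id <= prev_frame:
            raise OrderingError(
                f"frame_id {posture.frame_id} not after {prev_frame}"
            )
        if prev_t is not None and posture.t < prev_t - EPS:
            raise OrderingError("timestamps must be non-decreasing")
        if not skeleton:
            skeleton = posture.skeleton
        step_actions = protocol.step(posture)
        actions.extend(step_actions)
        row = {"frame_id": posture.frame_id, "t": posture.t}
        for name in skeleton:
            bp = posture.parts[name]
            row[f"{name}_x"] = bp.x
            row[f"{name}_y"] = bp.y
            row[f"{name}_conf"] = bp.confidence if not bp.missing else 0.0
        row["experiment_status"] = protocol.status
        row["trial"] = protocol.trial_label
        row["time"] = (
            posture.t - prev_t if prev_t is not None else 1.0 / protocol.fps
        )
        records.append(row)
        prev_frame, prev_t, last = posture.frame_id, posture.t, posture
        if any(a.name == "end_session" for a in step_actions):
            end_reason = protocol.end_reason
            break

    if last is not None:
        actions.extend(protocol.finalize(last.frame_id, last.t))
    if end_reason is None:
        end_reason = "stream_end"

    columns = ["frame_id", "t"]
    for name in skeleton:
        columns += [f"{name}_x", f"{name}_y", f"{name}_conf"]
    columns += ["experiment_status", "trial", "time"]
    df = pd.DataFrame(records, columns=columns)
    return SessionLog(
        protocol=protocol.name,
        seed=protocol.seed,
        config=copy.deepcopy(protocol.config()),
        fps=protocol.fps,
        skeleton=tuple(skeleton),
        records=df,
        events=list(protocol.events),
        actions=actions,
        counters=copy.deepcopy(protocol.counters),
        end_reason=end_reason,
    )


def success_rate(log: SessionLog) -> float:
    """Fraction of positive trials whose reward was collected."""
    positives = log.counters.get("positive_trials_completed", 0)
    if positives == 0:
        raise ValueError("success rate undefined: no completed positive trials")
    return log.counters.get("successes", 0) / positives


def yoked_from_log(source: SessionLog, *, max_duration: float | None = None,
                   seed: int = 0) -> YokedProtocol:
    """Build a yoked replay protocol from a source session's events."""
    timeline = [
        (e.channel, e.onset_t, e.offset_t)
        for e in source.events
        if e.offset_t is not None
    ]
    if max_duration is None:
        max_duration = source.config.get("max_duration")
    return YokedProtocol(
        timeline, max_duration=max_duration, fps=source.fps, seed=seed
    )
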