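"""Synthetic sessions: ground-truthed kinematics and score-map rendering.

This module stands in for the camera plus pose-estimation network.  It
emulates a freely moving mouse in a circular or rectangular arena with a
three-point skeleton (nose, neck, tail root):

* the heading performs a circular random walk (wrapped Gaussian
  increments, optionally biased toward a target bearing during
  configured episodes);
* the body center (neck) takes a half-normal forward step along the
  heading plus isotropic Gaussian jitter, reflected at the arena
  boundary so that every body part stays inside;
* optionally, per-part score maps are rendered as unit-amplitude
  Gaussian bumps at the true coordinates plus i.i.d. Gaussian noise
  clipped to [0, 1], mimicking the confidence rasters a pose-estimation
  network emits.

Every stochastic path is driven by a single integer seed; identical
(arena, params, seed) produce bitwise-identical tracks and maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .geometry import heading_unit, vec_angle_deg, wrap_deg
from .posture import DEFAULT_SKELETON, BodyPart, Posture

__all__ = [
    "KinematicsParams",
    "BiasEpisode",
    "GroundTruthTrack",
    "TrackFrame",
    "ScoreMapStack",
    "simulate_trajectory",
    "render_score_maps",
    "track_from_arrays",
]


@dataclass(frozen=True)
class BiasEpisode:
    """Interval during which heading increments drift toward a bearing."""

    start: float  # s
    end: float  # s
    target_bearing: float  # deg
    gain: float  # in [0, 1]; 1 snaps the mean increment fully to target

    def __post_init__(self):
        if not 0.0 <= self.gain <= 1.0:
            raise ValueError("bias gain must lie in [0, 1]")
        if self.end <= self.start:
            raise ValueError("bias episode must have end > start")


@dataclass(frozen=True)
class KinematicsParams:
    """Parameters of the simulated animal's movement process.

    step_sd is the scale (px/frame) of the half-normal forward step;
    heading_sd the standard deviation (deg/frame) of the wrapped
    Gaussian heading increments.  nose_offset and tail_offset place the
    nose and tail root along the heading axis relative to the neck; the
    defaults give a ~45 px nose-to-tail-root body consistent with a
    ~60 px mouse in a 848x480 px recording.
    """

    step_sd: float = 3.0
    heading_sd: float = 5.0
    nose_offset: float = 15.0
    tail_offset: float = 30.0
    bias_episodes: tuple[BiasEpisode, ...] = field(default_factory=tuple)
    seed: int = 0
    start_position: tuple[float, float] | None = None  # default: arena center
    start_heading: float = 0.0

    def __post_init__(self):
        if self.step_sd < 0 or self.heading_sd < 0:
            raise ValueError("step_sd and heading_sd must be >= 0")
        if self.nose_offset <= 0 or self.tail_offset <= 0:
            raise ValueError("nose_offset and tail_offset must be > 0")

    def to_dict(self) -> dict:
        return {
            "step_sd": self.step_sd,
            "heading_sd": self.heading_sd,
            "nose_offset": self.nose_offset,
            "tail_offset": self.tail_offset,
            "bias_episodes": [
                [b.start, b.end, b.target_bearing, b.gain] for b in self.bias_episodes
            ],
            "seed": self.seed,
            "start_position": None
            if self.start_position is None
            else list(self.start_position),
            "start_heading": self.start_heading,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KinematicsParams":
        eps = tuple(BiasEpisode(*b) for b in d.get("bias_episodes", []))
        return cls(
            step_sd=float(d.get("step_sd", 3.0)),
            heading_sd=float(d.get("heading_sd", 5.0)),
            nose_offset=float(d.get("nose_offset", 15.0)),
            tail_offset=float(d.get("tail_offset", 30.0)),
            bias_episodes=eps,
            seed=int(d.get("seed", 0)),
            start_position=tuple(d["start_position"])
            if d.get("start_position")
            else None,
            start_heading=float(d.get("start_heading", 0.0)),
        )


@dataclass(frozen=True)
class TrackFrame:
    """One frame of a ground-truth track."""

    frame_id: int
    t: float
    position: tuple[float, float]
    heading: float
    parts: Mapping[str, tuple[float, float]]


@dataclass
class GroundTruthTrack:
    """Per-frame ground truth: position, heading and body-part coordinates.

    The neck coincides with the body center; nose and tail root lie on
    the heading axis at the configured offsets.  ``t = frame_id / fps``.
    """

    arena: ArenaSpec
    frame_id: np.ndarray  # (n,) int
    t: np.ndarray  # (n,) s
    x: np.ndarray  # (n,) neck x, px
    y: np.ndarray  # (n,) neck y, px
    heading: np.ndarray  # (n,) deg in (-180, 180]
    nose_offset: float
    tail_offset: float

    def __post_init__(self):
        n = len(self.frame_id)
        for arr in (self.t, self.x, self.y, self.heading):
            if len(arr) != n:
                raise ValueError("track arrays must share one length")
        if n and (np.diff(self.frame_id) <= 0).any():
            raise ValueError("frame_id must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frame_id)

    @property
    def fps(self) -> float:
        return self.arena.fps

    def part_xy(self, part: str) -> np.ndarray:
        """(n, 2) coordinates of one body part over the whole track."""
        ux, uy = heading_unit(self.heading)
        if part == "neck":
            return np.column_stack([self.x, self.y])
        if part == "nose":
            return np.column_stack(
                [self.x + self.nose_offset * ux, self.y + self.nose_offset * uy]
            )
        if part == "tail_root":
            return np.column_stack(
                [self.x - self.tail_offset * ux, self.y - self.tail_offset * uy]
            )
        raise KeyError(part)

    def frame(self, i: int) -> TrackFrame:
        parts = {p: tuple(self.part_xy(p)[i]) for p in DEFAULT_SKELETON}
        return TrackFrame(
            frame_id=int(self.frame_id[i]),
            t=float(self.t[i]),
            position=(float(self.x[i]), float(self.y[i])),
            heading=float(self.heading[i]),
            parts=parts,
        )

    def to_postures(self) -> list[Posture]:
        coords = {p: self.part_xy(p) for p in DEFAULT_SKELETON}
        out = []
        for i in range(self.n_frames):
            parts = {
                p: BodyPart(float(coords[p][i, 0]), float(coords[p][i, 1]))
                for p in DEFAULT_SKELETON
            }
            out.append(Posture(int(self.frame_id[i]), float(self.t[i]), parts))
        return out

    def angles_to_reference(self, reference_point=None) -> np.ndarray:
        """Signed head-direction angle to the reference point, per frame."""
        ref = (
            reference_point
            if reference_point is not None
            else self.arena.reference_point
        )
        bearing = vec_angle_deg(ref[0] - self.x, ref[1] - self.y)
        return wrap_deg(self.heading - bearing)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"frame_id": self.frame_id, "t": self.t}
        for p in DEFAULT_SKELETON:
            xy = self.part_xy(p)
            data[f"{p}_x"] = xy[:, 0]
            data[f"{p}_y"] = xy[:, 1]
        data["heading"] = self.heading
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ScoreMapStack:
    """Per-part score rasters for one frame; all values in [0, 1]."""

    frame_id: int
    maps: Mapping[str, np.ndarray]

    def __post_init__(self):
        for name, m in self.maps.items():
            if m.ndim != 2 or m.size == 0:
                raise ValueError(f"score map for {name!r} must be 2-D, non-empty")


def simulate_trajectory(
    arena: ArenaSpec, params: KinematicsParams, duration: float
) -> GroundTruthTrack:
    """Simulate a bounded random walk with circular-random-walk heading.

    Returns ``round(duration * fps)`` frames.  Identical inputs produce
    identical output.  During a bias episode the mean heading increment
    is rotated toward the target bearing by the episode gain.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    margin = max(params.nose_offset, params.tail_offset)
    _check_margin(arena, margin)

    fps = arena.fps
    n = int(round(duration * fps))
    rng = np.random.default_rng(params.seed)

    start = (
        params.start_position if params.start_position is not None else arena.center
    )
    if not arena.contains(*start, margin=margin):
        raise ValueError("start position too close to the arena boundary")

    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    x[0], y[0] = start
    heading[0] = wrap_deg(params.start_heading)

    # Per-frame draws: one heading increment, one step length, one 2-D
    # jitter; drawn frame-by-frame so the stream layout is stable.
    bias = _bias_lookup(params.bias_episodes, n, fps)
    for i in range(1, n):
        h = heading[i - 1]
        mean_inc = 0.0
        b = bias[i]
        if b is not None:
            target, gain = b
            mean_inc = gain * wrap_deg(target - h)
        inc = mean_inc + rng.normal(0.0, params.heading_sd)
        h_new = wrap_deg(h + inc)
        heading[i] = h_new

        step = abs(rng.normal(0.0, params.step_sd))
        jx, jy = rng.normal(0.0, params.step_sd / 2.0, size=2)
        ux, uy = heading_unit(h_new)
        px = x[i - 1] + step * ux + jx
        py = y[i - 1] + step * uy + jy
        x[i], y[i] = arena.reflect_inside(px, py, margin=margin)

    frame_id = np.arange(n, dtype=int)
    t = frame_id / fps
    return GroundTruthTrack(
        arena=arena,
        frame_id=frame_id,
        t=t,
        x=x,
        y=y,
        heading=heading,
        nose_offset=params.nose_offset,
        tail_offset=params.tail_offset,
    )


def track_from_arrays(
    arena: ArenaSpec,
    positions: Sequence[tuple[float, float]] | np.ndarray,
    headings: Sequence[float] | np.ndarray,
    nose_offset: float = 15.0,
    tail_offset: float = 30.0,
) -> GroundTruthTrack:
    """Build a scripted ground-truth track from explicit positions/headings.

    Used for deterministic protocol tests (e.g. an agent that holds the
    target window, or visits regions on a fixed schedule).
    """
    positions = np.asarray(positions, dtype=float)
    headings = wrap_deg(np.asarray(headings, dtype=float))
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    if len(headings) != len(positions):
        raise ValueError("positions and headings must share one length")
    n = len(positions)
    frame_id = np.arange(n, dtype=int)
    return GroundTruthTrack(
        arena=arena,
        frame_id=frame_id,
        t=frame_id / arena.fps,
        x=positions[:, 0].copy(),
        y=positions[:, 1].copy(),
        heading=np.atleast_1d(headings).astype(float),
        nose_offset=nose_offset,
        tail_offset=tail_offset,
    )


def render_score_maps(
    frame: TrackFrame | Posture,
    H: int,
    W: int,
    bump_sd: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScoreMapStack:
    """Render per-part score maps: a unit Gaussian bump plus clipped noise.

    Each part's map holds ``exp(-d^2 / (2 bump_sd^2))`` around its true
    coordinate (amplitude exactly 1 at the coordinate itself when it
    falls on the integer grid), plus i.i.d. N(0, noise_sd) noise, with
    the sum clipped to [0, 1].
    """
    if bump_sd <= 0:
        raise ValueError("bump_sd must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(frame, Posture):
        parts = {name: (bp.x, bp.y) for name, bp in frame.parts.items()}
        frame_id = frame.frame_id
    else:
        parts = dict(frame.parts)
        frame_id = frame.frame_id

    rng = np.random.default_rng(seed)
    cols = np.arange(W)[None, :]
    rows = np.arange(H)[:, None]
    maps = {}
    for name, (px, py) in parts.items():
        if not (0 <= px <= W - 1 and 0 <= py <= H - 1):
            raise ValueError(
                f"part {name!r} at ({px}, {py}) lies outside the {H}x{W} raster"
            )
        d2 = (cols - px) ** 2 + (rows - py) ** 2
        m = np.exp(-d2 / (2.0 * bump_sd * bump_sd))
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, size=m.shape)
        maps[name] = np.clip(m, 0.0, 1.0)
    return ScoreMapStack(frame_id=frame_id, maps=maps)


def render_track(
    track: GroundTruthTrack, H: int, W: int, bump_sd: float, noise_sd=0.0, seed=0
) -> Iterator[ScoreMapStack]:
    """Lazily render score maps for every frame of a track."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(track.n_frames)
    for i in range(track.n_frames):
        yield render_score_maps(
            track.frame(i), H, W, bump_sd, noise_sd=noise_sd, seed=int(child_seeds[i])
        )


def _bias_lookup(episodes, n, fps):
    if not episodes:
        return [None] * n
    out = [None] * n
    for ep in episodes:
        lo = max(0, int(np.ceil(ep.start * fps)))
        hi = min(n, int(np.ceil(ep.end * fps)))
        for i in range(lo, hi):
            out[i] = (ep.target_bearing, ep.gain)
    return out


def _check_margin(arena: ArenaSpec, margin: float):
    if arena.shape == "circle":
        if margin >= float(arena.size):
            raise ValueError("nose/tail offsets larger than the arena radius")
    else:
        w, h = arena.size
        if 2 * margin >= min(w, h):
            raise ValueError("nose/tail offsets larger than the arena size")
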