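"""Posture-based trigger predicates.

A trigger inspects one posture (or a short history) and decides whether
to fire, returning a :class:`TriggerResult` with a diagnostic payload
(the measured angle, ROI id or speed) whether or not it fired.  All
triggers refuse to fire when a required body part is missing; the
payload then names the missing parts.

Angle convention: the head-direction angle is the signed angle from the
bearing (axis origin -> reference point) to the heading vector
(axis origin -> axis tip), positive counterclockwise on the y-flipped
image plane, wrapped to (-180, 180].  Symmetric windows only use its
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .arena import ROI
from .geometry import UndefinedAngleError, vec_angle_deg, wrap_deg
from .posture import Posture

__all__ = [
    "HeadDirectionWindow",
    "TriggerResult",
    "angle_to_reference",
    "head_direction_trigger",
    "region_trigger",
    "proximity_facing_trigger",
    "screen_facing_trigger",
    "speed_trigger",
]

# Angular comparisons close their boundary with a tiny slack so that a
# frame measured exactly on the window edge fires deterministically.
ANG_EPS = 1e-9


@dataclass(frozen=True)
class HeadDirectionWindow:
    """Angular target window around a reference point.

    ``width`` is the full window (e.g. 60 means +/-30 around the
    reference bearing).  ``axis`` names the (from, to) parts whose
    difference vector defines the heading.
    """

    reference_point: tuple[float, float]
    width: float = 60.0
    axis: tuple[str, str] = ("neck", "nose")

    def __post_init__(self):
        if not 0.0 < self.width <= 360.0:
            raise ValueError("window width must lie in (0, 360]")


@dataclass(frozen=True)
class TriggerResult:
    """Fire decision plus diagnostics for one frame."""

    fired: bool
    frame_id: int
    payload: Mapping[str, object] = field(default_factory=dict)


def _missing_result(posture: Posture, names) -> TriggerResult:
    return TriggerResult(
        fired=False,
        frame_id=posture.frame_id,
        payload={"missing_parts": tuple(names)},
    )


def angle_to_reference(posture: Posture, window: HeadDirectionWindow) -> float:
    """Signed head-direction angle to the window's reference point, deg.

    Raises :class:`UndefinedAngleError` if the axis parts coincide.
    """
    frm, to = window.axis
    ax, ay = posture.xy(frm)
    bx, by = posture.xy(to)
    heading = vec_angle_deg(bx - ax, by - ay)  # raises on zero-length axis
    rx, ry = window.reference_point
    if rx == ax and ry == ay:
        raise UndefinedAngleError("reference point coincides with the axis origin")
    bearing = vec_angle_deg(rx - ax, ry - ay)
    return wrap_deg(heading - bearing)


def head_direction_trigger(
    posture: Posture, window: HeadDirectionWindow
) -> TriggerResult:
    """Fire when |angle to reference| <= width/2 (closed interval)."""
    missing = posture.missing_parts(window.axis)
    if missing:
        return _missing_result(posture, missing)
    angle = angle_to_reference(posture, window)
    fired = abs(angle) <= window.width / 2.0 + ANG_EPS
    return TriggerResult(fired=fired, frame_id=posture.frame_id,
                         payload={"angle": angle})


def region_trigger(posture: Posture, roi: ROI, part: str = "nose") -> TriggerResult:
    """Fire when the part lies within the closed ROI disk."""
    if posture.is_missing(part):
        return _missing_result(posture, (part,))
    x, y = posture.xy(part)
    fired = roi.contains(x, y)
    return TriggerResult(
        fired=fired,
        frame_id=posture.frame_id,
        payload={"roi": roi.id, "distance": roi.distance(x, y)},
    )


def proximity_facing_trigger(
    posture: Posture,
    point: tuple[float, float],
    radius: float,
    facing_width: float,
    proximity_part: str = "neck",
    axis: tuple[str, str] = ("neck", "nose"),
) -> TriggerResult:
    """Fire when near a point AND facing it.

    The proximity condition tests the neck (body position) against a
    closed disk around the point; the facing condition tests the
    head-direction angle to the point against +/- facing_width/2.
    """
    needed = {proximity_part, *axis}
    missing = posture.missing_parts(tuple(needed))
    if missing:
        return _missing_result(posture, missing)
    prox = region_trigger(
        posture, ROI(id="proximity", center=tuple(point), radius=radius),
        part=proximity_part,
    )
    window = HeadDirectionWindow(reference_point=tuple(point),
                                 width=facing_width, axis=axis)
    facing = head_direction_trigger(posture, window)
    return TriggerResult(
        fired=prox.fired and facing.fired,
        frame_id=posture.frame_id,
        payload={
            "angle": facing.payload.get("angle"),
            "distance": prox.payload.get("distance"),
        },
    )


def screen_facing_trigger(
    posture: Posture,
    inward_normal_deg: float,
    width: float = 180.0,
    axis: tuple[str, str] = ("neck", "nose"),
) -> TriggerResult:
    """Fire when the heading lies within +/- width/2 of the screen normal.

    With the default 180 deg window this means the animal is looking
    toward the screen half-plane; a heading exactly parallel to the
    screen (90 deg off the normal) still fires (closed boundary).
    """
    missing = posture.missing_parts(axis)
    if missing:
        return _missing_result(posture, missing)
    frm, to = axis
    ax, ay = posture.xy(frm)
    bx, by = posture.xy(to)
    heading = vec_angle_deg(bx - ax, by - ay)
    angle = wrap_deg(heading - inward_normal_deg)
    fired = abs(angle) <= width / 2.0 + ANG_EPS
    return TriggerResult(fired=fired, frame_id=posture.frame_id,
                         payload={"angle": angle})


def speed_trigger(
    recent: Sequence[Posture],
    part: str,
    threshold: float,
    smooth_window: int,
    fps: float,
) -> TriggerResult:
    """Fire when the part's smoothed speed reaches ``threshold`` px/s.

    Speed is the mean frame-to-frame displacement of the part over the
    last ``smooth_window`` steps, multiplied by fps.  With fewer than
    two postures of history the speed is undefined and the trigger does
    not fire.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    if len(recent) < 2:
        frame_id = recent[-1].frame_id if recent else -1
        return TriggerResult(fired=False, frame_id=frame_id,
                             payload={"speed": None})
    tail = list(recent[-(smooth_window + 1):])
    missing = [p for p in tail if p.is_missing(part)]
    if missing:
        return _missing_result(tail[-1], (part,))
    xy = np.array([p.xy(part) for p in tail])
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed = float(disp.mean() * fps)
    return TriggerResult(
        fired=speed >= threshold,
        frame_id=tail[-1].frame_id,
        payload={"speed": speed},
    )
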