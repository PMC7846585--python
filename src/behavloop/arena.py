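"""Arena descriptions: geometry, regions of interest and walls.

An arena is either a disk or an axis-aligned rectangle in pixel (image)
coordinates.  Rectangular arenas span ``[0, width] x [0, height]``;
circular arenas are described by a center and radius.  The reference
point used by head-direction triggers may lie outside the arena (it is a
direction anchor, not a physical location).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ROI", "ArenaSpec", "WALL_NORMALS_DEG"]

# Inward normals of rectangle walls, math convention on the y-flipped
# plane: the top wall of the image faces down into the arena (-90 deg).
WALL_NORMALS_DEG = {"top": -90.0, "bottom": 90.0, "left": 0.0, "right": 180.0}


@dataclass(frozen=True)
class ROI:
    """Circular region of interest (closed disk)."""

    id: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"ROI {self.id!r}: radius must be > 0")

    def contains(self, x: float, y: float) -> bool:
        dx = x - self.center[0]
        dy = y - self.center[1]
        return dx * dx + dy * dy <= self.radius * self.radius

    def distance(self, x: float, y: float) -> float:
        return float(np.hypot(x - self.center[0], y - self.center[1]))


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the experimental arena.

    Parameters
    ----------
    shape : {"circle", "rectangle"}
    size : float or (float, float)
        Radius (circle) or width x height (rectangle), pixels.
    reference_point : (float, float)
        Anchor of the 0 deg head direction; may lie outside the arena.
    center : (float, float), optional
        Circle center; defaults to (radius, radius).  Ignored for
        rectangles (their center is width/2, height/2).
    cue_arc : (float, float), optional
        Angular span of a visual cue on the wall, degrees.
    rois : tuple of ROI
    screen_wall : str, optional
        Wall id carrying the stimulus screen ("top"/"bottom"/"left"/"right").
    fps : float
        Camera frame rate, frames per second.
    """

    shape: str
    size: float | tuple[float, float]
    reference_point: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] | None = None
    cue_arc: tuple[float, float] | None = None
    rois: tuple[ROI, ...] = field(default_factory=tuple)
    screen_wall: str | None = None
    fps: float = 30.0

    def __post_init__(self):
        if self.shape not in ("circle", "rectangle"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.shape == "circle":
            if np.ndim(self.size) != 0:
                raise ValueError("circle arena size is a scalar radius")
            if self.center is None:
                r = float(self.size)
                object.__setattr__(self, "center", (r, r))
        else:
            if np.ndim(self.size) == 0 or len(self.size) != 2:
                raise ValueError("rectangle arena size is (width, height)")
            w, h = self.size
            object.__setattr__(self, "center", (w / 2.0, h / 2.0))
        if self.screen_wall is not None and self.screen_wall not in WALL_NORMALS_DEG:
            raise ValueError(f"unknown wall id {self.screen_wall!r}")
        for roi in self.rois:
            if not self.contains(*roi.center):
                raise ValueError(f"ROI {roi.id!r} center lies outside the arena")

    # -- geometry --------------------------------------------------------

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        if self.shape == "circle":
            r = float(self.size) - margin
            return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= r * r + 1e-9
        w, h = self.size
        return (margin - 1e-9 <= x <= w - margin + 1e-9) and (
            margin - 1e-9 <= y <= h - margin + 1e-9
        )

    def reflect_inside(self, x: float, y: float, margin: float = 0.0):
        """Reflect a point at the (margin-shrunk) arena boundary.

        Points that would still fall outside after one reflection (very
        large steps) are clamped onto the boundary.
        """
        if self.shape == "circle":
            r = float(self.size) - margin
            cx, cy = self.center
            d = np.hypot(x - cx, y - cy)
            if d <= r or d == 0.0:
                return x, y
            new_d = 2.0 * r - d
            new_d = min(max(new_d, 0.0), r)
            scale = new_d / d
            return cx + (x - cx) * scale, cy + (y - cy) * scale
        w, h = self.size
        return (
            _reflect_interval(x, margin, w - margin),
            _reflect_interval(y, margin, h - margin),
        )

    def wall_inward_normal_deg(self, wall: str | None = None) -> float:
        """Inward normal of a rectangle wall (math convention, degrees)."""
        wall = wall if wall is not None else self.screen_wall
        if wall is None:
            raise ValueError("no wall specified and no screen_wall configured")
        if self.shape != "rectangle":
            raise ValueError("walls are defined for rectangular arenas only")
        return WALL_NORMALS_DEG[wall]

    def roi(self, roi_id: str) -> ROI:
        for r in self.rois:
            if r.id == roi_id:
                return r
        raise KeyError(roi_id)

    def with_rois(self, rois) -> "ArenaSpec":
        return replace(self, rois=tuple(rois))

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "size": self.size if np.ndim(self.size) == 0 else list(self.size),
            "reference_point": list(self.reference_point),
            "center": list(self.center),
            "cue_arc": None if self.cue_arc is None else list(self.cue_arc),
            "rois": [
                {"id": r.id, "center": list(r.center), "radius": r.radius}
                for r in self.rois
            ],
            "screen_wall": self.screen_wall,
            "fps": self.fps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        size = d["size"]
        if isinstance(size, (list, tuple)):
            size = tuple(float(v) for v in size)
        rois = tuple(
            ROI(r["id"], tuple(r["center"]), float(r["radius"]))
            for r in d.get("rois", [])
        )
        return cls(
            shape=d["shape"],
            size=size,
            reference_point=tuple(d.get("reference_point", (0.0, 0.0))),
            center=tuple(d["center"]) if d.get("center") else None,
            cue_arc=tuple(d["cue_arc"]) if d.get("cue_arc") else None,
            rois=rois,
            screen_wall=d.get("screen_wall"),
            fps=float(d.get("fps", 30.0)),
        )


def _reflect_interval(v: float, lo: float, hi: float) -> float:
    """Triangle-wave reflection of v into [lo, hi]."""
    if lo >= hi:
        raise ValueError("empty reflection interval (margin too large for arena)")
    span = hi - lo
    u = (v - lo) % (2.0 * span)
    if u > span:
        u = 2.0 * span - u
    return lo + u
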