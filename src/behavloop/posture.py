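"""Postures: named body-part coordinates for one frame.

A posture is the engine's unit of input: an ordered mapping from body
part name (nose, neck, tail_root by default) to an image coordinate with
a confidence value.  Parts that could not be detected on a frame carry
the last known coordinate and are flagged ``missing``; triggers refuse
to fire on frames where a required part is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["BodyPart", "Posture", "DEFAULT_SKELETON"]

DEFAULT_SKELETON = ("nose", "neck", "tail_root")


@dataclass(frozen=True)
class BodyPart:
    """One body part's estimated location on one frame."""

    x: float
    y: float
    confidence: float = 1.0
    missing: bool = False

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Posture:
    """Named body-part coordinates with timestamp for one frame."""

    frame_id: int
    t: float
    parts: Mapping[str, BodyPart] = field(default_factory=dict)

    @property
    def skeleton(self) -> tuple[str, ...]:
        return tuple(self.parts.keys())

    def xy(self, part: str) -> tuple[float, float]:
        p = self.parts[part]
        return (p.x, p.y)

    def is_missing(self, part: str) -> bool:
        return self.parts[part].missing

    def missing_parts(self, names=None) -> tuple[str, ...]:
        names = names if names is not None else self.skeleton
        return tuple(n for n in names if self.parts[n].missing)

    def as_array(self, names=None) -> np.ndarray:
        names = names if names is not None else self.skeleton
        return np.array([[self.parts[n].x, self.parts[n].y] for n in names])


def make_posture(frame_id, t, coords: Mapping[str, tuple], confidence=1.0) -> Posture:
    """Build a posture from bare (x, y) coordinates; convenience helper."""
    parts = {
        name: BodyPart(float(x), float(y), confidence=confidence)
        for name, (x, y) in coords.items()
    }
    return Posture(int(frame_id), float(t), parts)
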