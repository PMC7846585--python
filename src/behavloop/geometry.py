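"""Planar geometry in image coordinates.

All coordinates follow the raster convention: origin at the top-left
corner, x increasing rightward, y increasing downward (the frame of the
score maps).  Angles, however, are reported in the mathematical
convention on the y-flipped plane: counterclockwise positive, in
degrees, wrapped to the half-open interval (-180, 180].  A heading of
0 deg points right, +90 deg points *up* in the image.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "vec_angle_deg",
    "heading_unit",
    "ang_diff_deg",
    "UndefinedAngleError",
]


class UndefinedAngleError(ValueError):
    """Raised when an angle is requested for a zero-length vector."""


def wrap_deg(angle):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    if np.isscalar(angle) or wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def vec_angle_deg(dx, dy):
    """Angle of an image-coordinate vector on the y-flipped plane.

    Raises :class:`UndefinedAngleError` for a zero vector (scalar input
    only; array input propagates the atan2 convention of 0.0).
    """
    dx_a = np.asarray(dx, dtype=float)
    dy_a = np.asarray(dy, dtype=float)
    if dx_a.ndim == 0 and dx_a == 0.0 and dy_a == 0.0:
        raise UndefinedAngleError("angle of a zero-length vector is undefined")
    ang = np.degrees(np.arctan2(-dy_a, dx_a))
    out = wrap_deg(ang)
    return out


def heading_unit(angle_deg):
    """Unit vector (image coordinates) for a heading angle in degrees."""
    rad = np.radians(angle_deg)
    return np.cos(rad), -np.sin(rad)


def ang_diff_deg(a, b):
    """Signed difference a - b wrapped to (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
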