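import numpy as np
import pytest

from behavloop import ArenaSpec, KinematicsParams, simulate_trajectory


@pytest.fixture
def circle_arena():
    """Circular arena in a 848x480 raster with an external reference point."""
    return ArenaSpec(
        "circle",
        200.0,
        center=(424.0, 240.0),
        reference_point=(724.0, 240.0),
        fps=30.0,
    )


@pytest.fixture
def rect_arena():
    return ArenaSpec("rectangle", (480.0, 480.0), fps=30.0, screen_wall="top")


@pytest.fixture
def short_track(circle_arena):
    """One minute of seeded random-walk kinematics."""
    return simulate_trajectory(circle_arena, KinematicsParams(seed=42), 60.0)
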