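import numpy as np
import pytest

from shapechain import DesignProfile, TargetProfile, resample_to_target


@pytest.fixture
def square_target() -> TargetProfile:
    """Closed square of side 10 resampled at piece length 1 (40 pieces)."""
    pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], dtype=float)
    return resample_to_target(DesignProfile("square", pts, closed=True), 1.0)


@pytest.fixture
def line_target() -> TargetProfile:
    """Straight open profile of 12 unit pieces."""
    pts = np.column_stack([np.arange(13.0), np.zeros(13)])
    return TargetProfile("line", pts, piece_length=1.0)


def regular_polygon_target(n: int) -> TargetProfile:
    """Closed regular n-gon with vertices on the unit circle, one piece per side."""
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([np.cos(ang), np.sin(ang)])
    pts = np.vstack([pts, pts[0]])
    side = float(np.linalg.norm(pts[1] - pts[0]))
    return TargetProfile(f"ngon{n}", pts, piece_length=side, closed=True)


@pytest.fixture
def circle_target() -> TargetProfile:
    """Smooth closed circle polyline (radius 20, 120 pieces)."""
    return regular_polygon_target(120)
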