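import numpy as np
import pytest

from swallowreg.preprocess import PointSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return PointSet(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


def dense_circle(radius=10.0, n=20000, center=(0.0, 0.0)):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return PointSet(np.column_stack([
        center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)
    ]))


def dense_square(side, offset=(0.0, 0.0), pts_per_side=50):
    """Axis-aligned square sampled densely along its edges (corners included)."""
    t = np.linspace(0.0, side, pts_per_side, endpoint=False)
    o = np.asarray(offset, dtype=float)
    bottom = np.column_stack([t, np.zeros_like(t)])
    right = np.column_stack([np.full_like(t, side), t])
    top = np.column_stack([side - t, np.full_like(t, side)])
    left = np.column_stack([np.zeros_like(t), side - t])
    return PointSet(np.vstack([bottom, right, top, left]) + o)
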