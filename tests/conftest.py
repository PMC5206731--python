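import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fiberalign as fa

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 20260922


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def straight_fiber(fid, start, angle_deg, length):
    """Two-vertex fiber from `start` at the given axial angle (image convention)."""
    rad = np.radians(angle_deg)
    d = np.array([np.cos(rad), -np.sin(rad)]) * length
    return fa.FiberPath(fid, np.array([start, np.asarray(start, float) + d]))


def make_cell(length, angle=30.0, position=(50.0, 50.0), n=20):
    vec = fa.AlignmentVector(length, angle, n, position)
    return fa.GridCell(position, "valid", vec, n)


def make_stack(lengths, grid=None, z_spacing=1.0, pixel_size=1.0):
    """StackField with one slice holding one valid cell per requested length."""
    grid = grid or fa.GridSpec(512, 512)
    cells = [make_cell(l, position=(100.0 + 5 * i, 100.0)) for i, l in enumerate(lengths)]
    return fa.StackField(
        [fa.VectorField(grid, cells, z_index=0, z_spacing=z_spacing, pixel_size=pixel_size)]
    )
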