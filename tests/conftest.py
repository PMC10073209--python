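import numpy as np
import pytest

from minitms.coil import CoilSpec, default_mouse_coil
from minitms.constants import MU_0
from minitms.fields import build_winding
from minitms.phantom import default_phantom


@pytest.fixture(scope="session")
def mouse_spec() -> CoilSpec:
    return default_mouse_coil()

@pytest.fixture(scope="session")
def fig8_spec() -> CoilSpec:
    return default_mouse_coil(topology="figure8")


@pytest.fixture(scope="session")
def mouse_winding(mouse_spec):
    return build_winding(mouse_spec)


@pytest.fixture(scope="session")
def fig8_winding(fig8_spec):
    return build_winding(fig8_spec)


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


def segment_biot_savart(
    radius_mm: float,
    current_A: float,
    points_mm: np.ndarray,
    center_mm=(0.0, 0.0, 0.0),
    n_segments: int = 1024,
) -> np.ndarray:
    """Independent brute-force oracle: polygonal Biot-Savart for one circular
    loop in the z=0 plane, returning B (tesla) at each point."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_segments + 1)
    a = radius_mm * 1e-3
    nodes = np.column_stack(
        [a * np.cos(theta), a * np.sin(theta), np.zeros_like(theta)]
    ) + np.asarray(center_mm) * 1e-3
    mids = 0.5 * (nodes[:-1] + nodes[1:])
    dl = np.diff(nodes, axis=0)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) * 1e-3
    out = np.zeros_like(pts)
    for i, p in enumerate(pts):
        r = p - mids
        norm = np.linalg.norm(r, axis=1)
        out[i] = (
            MU_0 * current_A / (4.0 * np.pi) * (np.cross(dl, r) / norm[:, None] ** 3).sum(axis=0)
        )
    return out
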