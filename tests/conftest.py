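import numpy as np
import pytest

from podmetrics import synthetic
from podmetrics.imaging import Contour


@pytest.fixture(scope="session")
def basic_scene():
    """One straight-pod scene plus its render; shared read-only."""
    spec = synthetic.random_scene(5, seed=42)
    img, gt = synthetic.render_scene(spec)
    return spec, img, gt


@pytest.fixture
def disk_mask():
    """Rasterized disk of radius 50 centered in a 120x120 grid."""
    yy, xx = np.mgrid[:120, :120]
    return (xx - 60.0) ** 2 + (yy - 60.0) ** 2 <= 50.0**2


def square_contour(side: float = 10.0) -> Contour:
    return Contour([(0, 0), (side, 0), (side, side), (0, side)])


def random_simple_polygon(rng: np.random.Generator, n: int = 12) -> Contour:
    """Star-shaped (hence simple) polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(2.0, 10.0, size=n)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return Contour(pts)
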