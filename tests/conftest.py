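import numpy as np
import pytest

from dynfield.geometry import FieldGeometry


@pytest.fixture
def geo1d() -> FieldGeometry:
    """1-D feature space [0, 10) sampled at spacing 0.1."""
    return FieldGeometry(("x",), (0.0,), (10.0,), (100,))


@pytest.fixture
def geo2d() -> FieldGeometry:
    return FieldGeometry(("x", "y"), (0.0, 0.0), (1.0, 1.0), (24, 24))


@pytest.fixture
def geo3d() -> FieldGeometry:
    """Small (x, y, hue) space with a circular hue dimension."""
    return FieldGeometry(
        ("x", "y", "hue"),
        (0.0, 0.0, 0.0),
        (1.0, 1.0, 1.0),
        (12, 12, 8),
        (False, False, True),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def gaussian_bump(geometry: FieldGeometry, center, sigma, amplitude=1.0):
    """Gaussian input pattern on a grid, used as a localized probe."""
    mesh = geometry.meshgrid()
    z = sum(
        ((mesh[d] - center[d]) / sigma[d]) ** 2 for d in range(geometry.ndim)
    )
    return amplitude * np.exp(-0.5 * z)
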