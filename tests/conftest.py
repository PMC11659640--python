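import numpy as np
import pytest

from palatwin.synthetic_data import PalateShapeParams, generate_palate_mesh


@pytest.fixture(scope="session")
def default_cast():
    """One symmetric synthetic cast at moderate tessellation, with truth."""
    params = PalateShapeParams(edge_length=0.5)
    return generate_palate_mesh(params)


@pytest.fixture(scope="session")
def fine_cast():
    """Finer tessellation for area/volume accuracy checks."""
    params = PalateShapeParams(edge_length=0.25)
    return generate_palate_mesh(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20250917)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
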