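import numpy as np
import pytest

import mtled
from mtled.approximation import build_shape_table


@pytest.fixture(scope="session")
def small_grid():
    """Coarse homogeneous cylinder (~800 nodes) shared by cheap tests."""
    return mtled.generate_cylinder_grid(15.0, 17.0, 800, seed=1)


@pytest.fixture(scope="session")
def small_table(small_grid):
    return build_shape_table(small_grid.nodes, small_grid.quad_points)


@pytest.fixture(scope="session")
def ogden_gel():
    """Ogden parameters of the silicone-gel surrogate (a=-1.3, mu=722 Pa)."""
    return mtled.MaterialParams(a=-1.3, mu=722.0, D=5.57738e-5, name="gel")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_deformation_gradient(rng, scale=0.3):
    """Random F with positive determinant (resampled until J > 0.05)."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.05:
            return F
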