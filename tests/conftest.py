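import numpy as np
import pytest

from fastires.forward import NoiseModel, threeshell_leadfield
from fastires.mesh import (build_gradient_operator, fibonacci_sphere, flat_grid,
                           icosphere)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid_mesh():
    """Flat 6 x 5 triangulated grid (N=30) used for small solver instances."""
    return flat_grid(6, 5, spacing=5.0)


@pytest.fixture(scope="session")
def sphere_mesh():
    """162-vertex icosphere at 70 mm radius."""
    return icosphere(2, radius=70.0)


@pytest.fixture(scope="session")
def electrodes64():
    return fibonacci_sphere(64, radius=92.0).vertices


@pytest.fixture(scope="session")
def head_small(sphere_mesh, electrodes64):
    """Small spherical head model: 162-source mesh, 64 electrodes."""
    lf = threeshell_leadfield(sphere_mesh, electrodes64)
    grad = build_gradient_operator(sphere_mesh)
    return sphere_mesh, lf, grad


@pytest.fixture(scope="session")
def head_medium(electrodes64):
    """Medium spherical head model for pipeline-level checks (N=400)."""
    mesh = fibonacci_sphere(400, radius=70.0)
    lf = threeshell_leadfield(mesh, electrodes64)
    grad = build_gradient_operator(mesh)
    return mesh, lf, grad


@pytest.fixture(scope="session")
def head_1000(electrodes64):
    """Acceptance-scale spherical head model (N=1000 sources)."""
    mesh = fibonacci_sphere(1000, radius=70.0)
    lf = threeshell_leadfield(mesh, electrodes64)
    grad = build_gradient_operator(mesh)
    return mesh, lf, grad


@pytest.fixture
def white_noise64():
    return NoiseModel(sigma=np.eye(64))
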