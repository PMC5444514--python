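import numpy as np
import pytest

from fm2d import DomainSpec, InterfaceMesh, make_shape


@pytest.fixture
def square_domain():
    return DomainSpec(rectangles=((-2.0, 2.0, -2.0, 2.0),))


@pytest.fixture
def diamond():
    """Square with vertices on the unit circle (the hand-computable case)."""
    return InterfaceMesh(np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]]))


def random_simple_polygon(rng, n=12, r0=1.0, wobble=0.35):
    """Star-shaped (hence simple) polygon with irregular radii/angles."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    # keep angles distinct
    th = th + np.linspace(0, 1e-3, n)
    r = r0 * (1.0 + wobble * rng.uniform(-1, 1, n))
    return InterfaceMesh(np.c_[r * np.cos(th), r * np.sin(th)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
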