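import numpy as np
import pytest

from symadapt import synthetic


@pytest.fixture(scope="session")
def water():
    return synthetic.water()


@pytest.fixture(scope="session")
def ammonia():
    return synthetic.ammonia()


@pytest.fixture(scope="session")
def methane():
    return synthetic.methane()


@pytest.fixture(scope="session")
def benzene():
    return synthetic.benzene()


@pytest.fixture(scope="session")
def ferrocene():
    return synthetic.ferrocene()


@pytest.fixture(scope="session")
def h3():
    return synthetic.h3_triangle()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    from symadapt.operations import rotation_matrix

    return rotation_matrix(axis, rng.uniform(0.0, 2.0 * np.pi))
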