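import numpy as np
import pytest

import spectmap as sm


@pytest.fixture(scope="session")
def default_bundle():
    return sm.generate_phantom(sm.default_liver_phantom())


@pytest.fixture(scope="session")
def default_model(default_bundle):
    """Full 128x128 system model with attenuation and detector response."""
    spec = sm.ExperimentSpec(seed=0)
    return sm.build_model(spec, default_bundle)


@pytest.fixture(scope="session")
def small_bundle():
    return sm.generate_phantom(sm.default_liver_phantom(64))


@pytest.fixture(scope="session")
def small_model(small_bundle):
    spec = sm.ExperimentSpec(phantom=sm.default_liver_phantom(64), seed=0)
    return sm.build_model(spec, small_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_model():
    """Dense 2-pixel / 3-bin system with strictly positive sensitivity."""
    A = np.array([[1.0, 0.2], [0.3, 1.0], [0.5, 0.5]])
    return sm.MatrixModel(A, image_shape=(1, 2), sino_shape=(3, 1))
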