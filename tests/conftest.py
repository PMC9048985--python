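import numpy as np
import pytest

from dcepk.aif import AIFParams
from dcepk.phantom import PhantomSpec, simulate_study
from dcepk.signal_model import AcquisitionParams


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def aifp():
    return AIFParams()


@pytest.fixture(scope="session")
def micro_spec():
    """Small single-lesion phantom for fast end-to-end tests."""
    from dcepk.phantom import LesionSpec
    return PhantomSpec(shape=(24, 24), n_slices=1, brain_radii=(9.5, 9.5),
                       lesions=(LesionSpec(center=(12, 12), radii=(4, 4)),),
                       noise_sigma=0.0, seed=123)


@pytest.fixture(scope="session")
def micro_study(micro_spec, aifp, acq):
    return simulate_study(micro_spec, aifp, acq)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
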