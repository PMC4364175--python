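import numpy as np
import pytest

from amygsim import NetworkParams


@pytest.fixture(scope="session")
def params():
    return NetworkParams()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free parameters for deterministic closed-form checks."""
    return NetworkParams(noise_level=0.0, randomize_fixed=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
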