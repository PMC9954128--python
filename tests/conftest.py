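import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def ssp_space_2d():
    from stnef.ssp import make_encoding_matrix

    return make_encoding_matrix(101, 2, "random", length_scale=0.5, seed=0)


@pytest.fixture(scope="session")
def ssp_space_1d():
    from stnef.ssp import make_encoding_matrix

    return make_encoding_matrix(101, 1, "random", length_scale=0.5, seed=1)


@pytest.fixture(scope="session")
def hex_space():
    from stnef.ssp import make_encoding_matrix

    return make_encoding_matrix(0, 2, "hex", length_scale=0.15, seed=0, scale_range=(1.0, 2.5))
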