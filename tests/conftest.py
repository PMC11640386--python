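import numpy as np
import pytest

from ihcquant.stain import default_hdab_matrix


@pytest.fixture(scope="session")
def hdab():
    return default_hdab_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
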