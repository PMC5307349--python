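import numpy as np
import pytest

import hurstlab as hl


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def path_h03():
    return hl.simulate_fbm(0.3, 256, 42)


@pytest.fixture(scope="session")
def path_h07():
    return hl.simulate_fbm(0.7, 256, 43)
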