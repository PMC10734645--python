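import numpy as np
import pytest

import trochwarp as tw


@pytest.fixture(scope="session")
def pooled_phantom():
    """Noise-free default pooled phantom, the reference measurement subject."""
    return tw.generate_phantom(tw.default_phantom_spec("pooled"), seed=1)


@pytest.fixture(scope="session")
def pooled_profile(pooled_phantom):
    return tw.measure_profile(pooled_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
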