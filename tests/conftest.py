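import numpy as np
import pytest
from hypothesis import settings

from isotroph.trophic import BaselineSignature

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20130814)


@pytest.fixture
def baseline_now():
    return BaselineSignature(site="NOW", d15n_sediment=7.4, d13c_sediment=-20.6, sd=0.1, n=3)


@pytest.fixture
def baseline_ls():
    return BaselineSignature(site="LS", d15n_sediment=8.3, d13c_sediment=-20.0, sd=0.3, n=3)
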