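import numpy as np
import pytest

from cmrquant.synthetic import PhantomConfig, generate_aif


@pytest.fixture
def config():
    return PhantomConfig(seed=42)


@pytest.fixture
def aif_curve(config):
    t, aif = generate_aif(config)
    return t, aif


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
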