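import numpy as np
import pytest

from eegfusion import SynthConfig, generate_dataset, make_hybrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_config():
    # short segments keep the CNN tests fast; all spectral structure intact
    return SynthConfig(n_per_class=6, length=512, seed=9)


@pytest.fixture(scope="session")
def short_segments(short_config):
    return generate_dataset(short_config)


@pytest.fixture(scope="session")
def short_hybrids(short_segments):
    return [make_hybrid(s) for s in short_segments]
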