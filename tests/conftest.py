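import numpy as np
import pytest

from abcscreen import RunConfig, SignalModelParams, StudyDesign, generate_timecourse


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def noiseless_params():
    return SignalModelParams(noise_sd=0.0)


@pytest.fixture
def design():
    return StudyDesign(chemical="TESTCHEM", max_concentration=40.0)


@pytest.fixture
def noiseless_plate(noiseless_params, design, config):
    return generate_timecourse(noiseless_params, design, config, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
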