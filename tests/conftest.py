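import numpy as np
import pytest

from poppyspread.synth import (
    SurveyProtocol,
    SynthConfig,
    make_landscape,
    render_luminance,
    sample_transect_survey,
    simulate_truth,
)


@pytest.fixture(scope="session")
def config():
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def landscape(config):
    return make_landscape(config)


@pytest.fixture(scope="session")
def truth(landscape, config):
    return simulate_truth(landscape, config)


@pytest.fixture(scope="session")
def transect_survey(truth, landscape, config):
    return sample_transect_survey(
        truth, landscape, SurveyProtocol(), config, seed=11
    )


@pytest.fixture(scope="session")
def scene(landscape, config):
    return render_luminance(landscape, config, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
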