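import numpy as np
import pytest

from petkin import phantom


@pytest.fixture(scope="session")
def schedule():
    return phantom.default_schedule()


@pytest.fixture(scope="session")
def blood():
    """Feng-form arterial input sampled densely over the 65-min protocol."""
    return phantom.analytic_input_function()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
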