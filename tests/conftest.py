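import numpy as np
import pytest

from sinudens import phantom


@pytest.fixture(scope="session")
def serous_phantom():
    """40% serous fluid preset at default 64-cube resolution."""
    return phantom.make_sinus_phantom(phantom.preset_config("serous_40"))


@pytest.fixture(scope="session")
def norm_phantom():
    return phantom.make_sinus_phantom(phantom.preset_config("conditional_norm"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
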