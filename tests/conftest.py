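import numpy as np
import pytest

from fcbtrace import GeneratorConfig, generate_spectra_set


@pytest.fixture(scope="session")
def default_spectra():
    """Default five-source synthetic set (90 x 300), fixed seed."""
    return generate_spectra_set(GeneratorConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
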