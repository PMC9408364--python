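import numpy as np
import pytest

from safesim import validate_config


@pytest.fixture
def default_config():
    return validate_config({})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def deterministic_config():
    """Zero-variance, certain-adoption limit: every worker is identical and
    the willingness-crossing tick has a closed form."""
    return validate_config(
        {
            "field_sd": 0,
            "worker_sd": 0,
            "adoption_prob": 1.0,
            "ticks": 60,
        }
    )
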