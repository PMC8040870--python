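import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("deterministic")

from heatscreen import TRAITS, generate_trial, six_cultivar_preset


@pytest.fixture(scope="session")
def preset_trial():
    """One six-cultivar trial with default replicate noise."""
    return generate_trial(six_cultivar_preset(), seed=11)


@pytest.fixture(scope="session")
def noiseless_trial():
    cfg = six_cultivar_preset()
    cfg.noise_sd = {t: 0.0 for t in TRAITS}
    return generate_trial(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
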