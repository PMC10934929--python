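import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_spectra():
    """A modest, clearly separable two-class SpectrumSet for fast tests."""
    from candlepls import GeneratorConfig, generate_spectra

    cfg = GeneratorConfig(n_fertile=40, n_nonfertile=6, seed=11)
    return generate_spectra(cfg)
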