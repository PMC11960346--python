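import numpy as np
import pytest
from hypothesis import settings

from coda24.simulate import GeneratorConfig, fixture_small, generate_participants

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def cohort():
    """Default-calibration synthetic cohort (n = 410)."""
    return generate_participants(GeneratorConfig(n=410, seed=12345))


@pytest.fixture(scope="session")
def mini():
    """Deterministic 12-participant fixture cohort."""
    return fixture_small()


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


def random_compositions(rng, n, total=1440.0):
    """Strictly positive random compositions closed to ``total``."""
    x = rng.lognormal(mean=np.log([300, 800, 150, 100]), sigma=0.5, size=(n, 4))
    return x * (total / x.sum(axis=1, keepdims=True))
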