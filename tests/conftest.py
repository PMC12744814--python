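import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


@pytest.fixture
def uniform_map_values(rng):
    """Random signed strain vectors with ~50% per-segment impairment at the
    default −15 cutoff — rich in boundary configurations."""
    def draw(n):
        return rng.uniform(-25.0, -5.0, size=(n, 18))
    return draw
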