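import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Factory for TissueSpec with all degradation modes off."""
    from adipocount import TissueSpec

    def make(seed: int = 0, **kw):
        params = dict(
            gap_fraction=0.0, n_debris=0, vignette_strength=0.0, rng_seed=seed
        )
        params.update(kw)
        return TissueSpec(**params)

    return make
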