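import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tesseloc import LocalizationSet, SimulationConfig, simulate_pair

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20190530)


@pytest.fixture
def csr_channel(rng):
    """A 2D complete-spatial-randomness channel on a 1000 nm field."""
    def _make(n=500, field=1000.0, channel_id="A", seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return LocalizationSet(r.random((n, 2)) * field, channel_id=channel_id)

    return _make


@pytest.fixture
def small_sim():
    """A small but fully structured two-channel cluster simulation."""
    def _make(d=0.0, seed=0, n_clusters=12, field=1200.0, density_B=0.013):
        cfg = SimulationConfig(
            d=d,
            n_clusters=n_clusters,
            field_size=(field, field),
            density_B=density_B,
            seed=seed,
        )
        return simulate_pair(cfg)

    return _make
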