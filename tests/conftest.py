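import pytest
from hypothesis import HealthCheck, settings

import isopart as ip

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_study():
    """All seven preset treatments, simulated and emitted without noise."""
    return ip.run_study(seed=1, noise=False)


@pytest.fixture(scope="session")
def noisy_study():
    """Seeded study at the default instrument-noise levels."""
    return ip.run_study(seed=7, noise=True)


@pytest.fixture(scope="session")
def enriched_ends():
    """Daphnia at -25 permil, leaves at 10 atom% 13C (the study endmembers)."""
    return ip.Endmembers(
        ip.IsotopeValue(-25.0),
        ip.IsotopeValue(0.10, ip.ATOM_FRACTION),
    )
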