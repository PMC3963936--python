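import pytest
from hypothesis import HealthCheck, settings

from stunmird import build_phantom, load_emission_spectrum

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tc99m():
    return load_emission_spectrum()


@pytest.fixture(scope="session")
def phantom54():
    """Default study phantom: 5.4 mg thyroid, 200 um voxels, 20 mm body."""
    return build_phantom(5.4, 200.0, 20.0)
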