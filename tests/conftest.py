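import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def probe_sources():
    from oxylight import build_led_sources, default_probe_config

    return build_led_sources(default_probe_config())


@pytest.fixture(scope="session")
def spectra():
    from oxylight import default_spectra

    return default_spectra()


@pytest.fixture(scope="session")
def small_homogeneous_medium():
    """Small soft-tissue block for fast Monte-Carlo unit tests."""
    from oxylight import Grid3D, MediumGrid, OpticalProperties

    grid = Grid3D(shape=(60, 60, 60), spacing_mm=0.148)
    labels = np.ones(grid.shape, dtype=np.uint8)
    props = {
        (1, 750): OpticalProperties(0.101, 10.5, 0.9),
        (1, 850): OpticalProperties(0.089, 9.0, 0.9),
    }
    return MediumGrid(grid, labels, props)
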