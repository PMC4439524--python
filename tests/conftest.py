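import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def freq_grid():
    from itdfreq.acoustics import default_freq_grid

    return default_freq_grid()


@pytest.fixture(scope="session")
def sphere_spec_90(freq_grid):
    """Bare-sphere IPD spectrum for a source at 90 degrees."""
    from itdfreq import acoustics as ac

    cfg = ac.HeadModelConfig(source_azimuth=90.0)
    return ac.ipd_spectrum(ac.sphere_hrtf(cfg, freq_grid), freq_grid, 90.0)


@pytest.fixture(scope="session")
def ground_spec_70(freq_grid):
    """Sphere + ground IPD spectrum for a source at 70 degrees."""
    from itdfreq import acoustics as ac

    ground = ac.GroundConfig()
    d = float(np.hypot(ground.horizontal_distance,
                       ground.source_height - ground.head_height))
    cfg = ac.HeadModelConfig(source_azimuth=70.0, source_distance=d)
    gains = ac.sphere_hrtf(cfg, freq_grid)
    gains = ac.add_ground_reflection(gains, cfg, ground, freq_grid)
    return ac.ipd_spectrum(gains, freq_grid, 70.0)
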