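import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_set():
    """Two shots on a 5-point grid."""
    from libsid.core import ShotMeta, SpectrumSet

    grid = np.linspace(300.0, 304.0, 5)
    intensities = np.array(
        [
            [0.1, 0.5, 2.0, 0.5, 0.1],
            [0.2, 0.6, 1.8, 0.4, 0.2],
        ]
    )
    meta = [
        ShotMeta(variety=1, sample_id="V1S01", site_id="T01"),
        ShotMeta(variety=2, sample_id="V2S01", site_id="T01"),
    ]
    return SpectrumSet(grid=grid, intensities=intensities, meta=meta)
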