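import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tubehct import CameraPose, TubeSpec
from tubehct.renderer import RenderConfig, render_tube

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: small raster for tests that only care about behaviour, not precision
SMALL = dict(width_px=96, height_px=400, noise_sigma=0.0)


@pytest.fixture(scope="session")
def nadir_sample():
    """A noise-free tube rendered straight from above, full resolution."""
    return render_tube(
        TubeSpec(true_hct_pct=42.0), CameraPose(), RenderConfig(noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def small_sample():
    """A noise-free tube on a small raster (fast tests)."""
    return render_tube(TubeSpec(true_hct_pct=42.0), CameraPose(), RenderConfig(**SMALL))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
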