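import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spectralbmd as sb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return sb.default_registry()


@pytest.fixture(scope="session")
def phantom():
    return sb.default_phantom()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless phantom scan at the reference 0.5 mm isotropic spacing."""
    return sb.rasterize_phantom(
        spacing_mm=0.5, noise=sb.NoiseSpec.none(), seed=1
    )


@pytest.fixture(scope="session")
def coarse_phantom():
    """Cheap coarse phantom scan for geometry-only tests."""
    return sb.rasterize_phantom(
        spacing_mm=(1.0, 1.0, 1.5), noise=sb.NoiseSpec.none(), seed=2
    )


@pytest.fixture(scope="session")
def noiseless_subject():
    """One mid-weight noiseless subject with phantom in the FOV."""
    rng = np.random.default_rng(42)
    spec = sb.make_subject("s_test", 12.0, rng)
    vol = sb.rasterize_subject(spec, noise=sb.NoiseSpec.none(), seed=5)
    return spec, vol
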