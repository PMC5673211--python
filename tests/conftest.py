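import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def breast_phantom_desk():
    """Seeded breast phantom at the desk preset (128^3, 0.8 mm)."""
    from bctsim.pipeline import generate_phantom

    phantom, info = generate_phantom(0)
    return phantom, info


@pytest.fixture(scope="session")
def coarse_support():
    """Boundary-only support (with skin) on a coarse grid, for growth tests."""
    from bctsim.phantom_boundary import AnatomyParams, generate_support

    rng = np.random.default_rng(7)
    return generate_support(AnatomyParams(), rng, voxel_mm=2.0)


@pytest.fixture(scope="session")
def cylinder_scan():
    """Fixture phantom + 180-angle fan sinograms (poly 60 kVp, mono 35 keV)."""
    from bctsim.fixtures import FixtureSpec, make_cylinder_fixture
    from bctsim.pipeline import simulate_sinograms
    from bctsim.projector import ScanGeometry

    spec = FixtureSpec()
    volume = make_cylinder_fixture(spec)
    geom = ScanGeometry(n_rows=1, n_cols=128, pixel_mm=1.2,
                        angles_deg=np.arange(180) * 2.0)
    sino_poly, sino_mono = simulate_sinograms(volume, geom)
    return spec, volume, geom, sino_poly, sino_mono
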