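import numpy as np
import pytest

from nirstopo import (
    MbllCoefficients,
    make_canonical_mesh,
    project_channels_disc,
    project_channels_sphere,
    stroop_probe_layout,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layout():
    """Synthetic 52-channel prefrontal probe."""
    return stroop_probe_layout()


@pytest.fixture(scope="session")
def probe_geometry(layout):
    """(unit channel directions, head center, head radius, disc xy [mm])."""
    dirs, center, radius = project_channels_sphere(layout)
    xy = project_channels_disc(dirs, radius)
    return dirs, center, radius, xy


@pytest.fixture(scope="session")
def coarse_mesh():
    return make_canonical_mesh(2)


@pytest.fixture
def coeffs():
    return MbllCoefficients.from_tables(wavelengths=(695.0, 830.0), age=30.0)
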