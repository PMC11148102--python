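import numpy as np
import pytest

from pelagoshift import geo, synthetic_data


@pytest.fixture
def small_grid():
    return geo.GridSpec(12.0, 24.0, -20.0, -12.0, 0.5)


@pytest.fixture
def meridional_coast():
    """Straight north-south coastline at lon -16, isobath 0.3 deg offshore."""
    lats = np.arange(10.0, 32.01, 1.0)
    coastline = np.column_stack([lats, np.full_like(lats, -16.0)])
    isobath = np.column_stack([lats, np.full_like(lats, -16.3)])
    return geo.CoastGeometry(coastline, isobath)


@pytest.fixture
def coarse_world_config():
    """Fast 1-degree world for integration tests."""
    return synthetic_data.WorldConfig(
        grid=geo.GridSpec(10.0, 32.0, -22.0, -10.0, 1.0), seed=42
    )


@pytest.fixture
def coarse_world(coarse_world_config):
    return synthetic_data.build_world(coarse_world_config)
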