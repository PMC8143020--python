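import numpy as np
import pytest

from visphys.geometry import MonitorSpec
from visphys.stimuli import build_catalog


@pytest.fixture(scope="session")
def monitor():
    return MonitorSpec()


@pytest.fixture(scope="session")
def small_monitor():
    """Downscaled raster (168x105) with the full visual extent."""
    return MonitorSpec().scaled(0.1)


@pytest.fixture(scope="session")
def catalog(small_monitor):
    return build_catalog(small_monitor)


@pytest.fixture(scope="session")
def tiny_catalog():
    """Very coarse raster for brute-force per-pixel oracles."""
    return build_catalog(MonitorSpec(width_px=100, height_px=60, px_per_deg=100 / 60.3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
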