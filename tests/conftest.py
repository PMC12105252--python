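import numpy as np
import pytest

from nichecircuit import LandscapeConfig, Raster, RasterStack


def make_raster(values, cell=100.0, nodata=None):
    """Raster from a 2-D array, NW corner at the origin."""
    values = np.asarray(values, dtype=float)
    return Raster.from_origin(
        values, 0.0, values.shape[0] * cell, cell, nodata=nodata
    )


@pytest.fixture(scope="session")
def landscape():
    """A small complete landscape shared across tests (read-only)."""
    from nichecircuit import generate_landscape

    cfg = LandscapeConfig(
        grid_shape=(80, 80),
        cell_size=100.0,
        n_climate_vars=4,
        autocorr_range=1500.0,
        seed=7,
        scenario_deltas={"warm": 0.8},
    )
    return generate_landscape(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
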