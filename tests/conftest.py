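import numpy as np
import pytest

from accessim.grid import GridSpec, Raster
from accessim.landscape import (
    LandscapeConfig,
    gen_facilities,
    gen_landscape,
    gen_population_rwi_urbanicity,
)


@pytest.fixture(scope="session")
def spec50():
    return GridSpec(n_rows=50, n_cols=50, cell_size=30.0)


@pytest.fixture(scope="session")
def landscape50(spec50):
    """One deterministic 50x50 study area shared across read-only tests."""
    dem, lc, roads, zones = gen_landscape(spec50, LandscapeConfig(), seed=11)
    pop, rwi, urb = gen_population_rwi_urbanicity(spec50, LandscapeConfig(), seed=12)
    registry = gen_facilities(spec50, seed=13, pop=pop, roads=roads)
    return dict(spec=spec50, dem=dem, landcover=lc, roads=roads, zones=zones,
                pop=pop, rwi=rwi, urb=urb, registry=registry)


def uniform_speed_raster(spec, v_ms, walking=True):
    """All-passable uniform speed surface (helper for closed-form checks)."""
    from accessim.friction import SpeedRaster

    return SpeedRaster(
        spec,
        np.full(spec.shape, v_ms, float),
        np.full(spec.shape, walking, bool),
    )


@pytest.fixture
def flat_dem():
    def make(spec, elevation=0.0):
        return Raster(spec, np.full(spec.shape, elevation, float))

    return make
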