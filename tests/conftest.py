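import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from impedimap.plate_model import MAP_KEYS, GRID_SHAPE, ParameterMapStack
from impedimap.synthetic_data import (
    ARCHETYPES,
    SimulationConfig,
    simulate_well,
)


def make_stack(well_id="A1", time_h=0.0, fill=1.0, rng=None):
    """A valid 27-map stack, constant or random positive."""
    maps = {}
    for k in MAP_KEYS:
        if rng is None:
            maps[k] = np.full(GRID_SHAPE, fill)
        else:
            maps[k] = rng.uniform(0.5, 1.5, GRID_SHAPE)
    return ParameterMapStack(well_id=well_id, scan_time_h=time_h, maps=maps)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(seed=0, duration_h=12.0, scan_interval_h=0.5).noiseless()


@pytest.fixture(scope="session")
def mdck_well(noiseless_cfg):
    """Noiseless barrier-forming epithelial well, 12 h at 30-min scans."""
    return simulate_well(
        ARCHETYPES["MDCK-like"], 1.0, noiseless_cfg, seed=7, density=15_000.0
    )
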