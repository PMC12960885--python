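import numpy as np
import pytest

from bcmap import PipelineConfig, SimulationConfig, generate_landscape, run_pipeline
from bcmap.grid import GridRaster


@pytest.fixture(scope="session")
def default_scene():
    """One standard synthetic scene shared by read-only tests."""
    return generate_landscape(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run on the standard scene."""
    return run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=1)))


@pytest.fixture
def make_raster():
    def _make(data, cell_size=10.0, dtype=None):
        arr = np.asarray(data, dtype=dtype)
        return GridRaster(arr, cell_size=cell_size)

    return _make


def small_wetland_config(**overrides) -> SimulationConfig:
    """A quick two-patch land-only configuration for cheap scene tests."""
    defaults = dict(
        seed=0,
        grid_width=160,
        grid_height=120,
        sea_fraction=0.3,
        patch_classes=("open_wetland", "forested_wetland"),
        stressor_layout=((4, 4), (2, 2)),
        patch_cells=60,
        n_basins=1,
        basin_modified_props=(30.0,),
        n_protected=1,
        protected_cover_target=0.4,
        n_field_points=20,
        gps_noise_sd=0.0,
        n_lakes=0,
        road_barrier=False,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
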