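import numpy as np
import pytest

from casanpp.grids import GridTransform, RasterGrid
from casanpp.grids import MonthIndex
from casanpp.synth import SceneRecipe, generate


def make_grid(values, cell_size=250.0, nodata=-9999.0, crs="local-albers"):
    values = np.asarray(values, dtype=float)
    transform = GridTransform.north_up(0.0, values.shape[0] * cell_size, cell_size)
    return RasterGrid(values, transform, nodata, crs)


@pytest.fixture
def template():
    return make_grid(np.zeros((8, 8)))


@pytest.fixture(scope="session")
def small_recipe():
    # desk-scale scene: 48x48 grid, hazard counts reduced proportionally
    return SceneRecipe(
        grid_shape=(48, 48), seed=7,
        hazard_counts={"landslide": 5, "collapse": 16, "debris_flow": 5},
    )


@pytest.fixture(scope="session")
def small_scene(small_recipe):
    return generate(small_recipe)


@pytest.fixture(scope="session")
def quake_months():
    return MonthIndex(2017, 7), MonthIndex(2017, 8), MonthIndex(2017, 9)
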