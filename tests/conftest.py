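import numpy as np
import pytest

from hstrend import Grid, RasterLayer, PredictorStack


@pytest.fixture
def grid4x5():
    return Grid(4, 5, origin_x=0.0, origin_y=4.0, cell_size=1.0)


@pytest.fixture
def masked_grid():
    mask = np.ones((4, 5), dtype=bool)
    mask[0, 0] = False
    mask[3, 4] = False
    return Grid(4, 5, origin_x=0.0, origin_y=4.0, cell_size=1.0, valid_mask=mask)


def make_stack(grid, years, predictor_values):
    """Build a PredictorStack from {name: {year: flat array}}."""
    layers = {}
    for name, by_year in predictor_values.items():
        for y in years:
            layers[(y, name)] = RasterLayer(grid, by_year[y])
    return PredictorStack(grid, list(years), list(predictor_values), layers)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
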