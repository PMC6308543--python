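import numpy as np
import pytest

from obforest.grids import GeoGrid, SceneStack


@pytest.fixture
def small_grid():
    return GeoGrid(10, 10, pixel_size=30.0)


def make_stack(band_values, dates=None, grid=None, mask=None):
    """Stack with constant band values: band_values = [(b1,b2,b3,b4), ...] per date."""
    dates = dates or [(2010, 7, 15)]
    n = len(dates)
    if grid is None:
        grid = GeoGrid(4, 4)
    data = np.zeros((n, 4, grid.n_rows, grid.n_cols))
    for d in range(n):
        for b in range(4):
            data[d, b] = band_values[d][b]
    if mask is None:
        mask = np.zeros((n, grid.n_rows, grid.n_cols), dtype=bool)
    return SceneStack(grid=grid, dates=dates, data=data, mask=mask)


@pytest.fixture
def flat_stack():
    return make_stack([(0.05, 0.08, 0.06, 0.45)])
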