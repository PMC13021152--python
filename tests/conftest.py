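import numpy as np
import pytest

from spatialsim import (
    Window,
    assign_cell_positivity,
    assign_holes,
    assign_tissue,
    create_simulation_object,
    generate_spatial_pattern,
)


@pytest.fixture
def unit_window():
    return Window(0, 1, 0, 1)


@pytest.fixture
def square_window():
    """The canonical 2x2 window centred at the origin."""
    return Window(-1, 1, -1, 1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim(square_window):
    """A fully assigned 5-sample simulation at the default scenario settings."""
    obj = create_simulation_object(5, square_window, n_cell_types=1, seed=101)
    generate_spatial_pattern(obj, 250)
    assign_holes(obj)
    assign_tissue(obj)
    assign_cell_positivity(obj)
    return obj
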