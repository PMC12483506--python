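import numpy as np
import pytest

from lspsmap.model_io import GridSpec


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture
def small_grid() -> GridSpec:
    """A 4x6 grid (single pseudo-layer) for fast sweep-level tests."""
    return GridSpec(n_cols=6, n_rows=4, l5a_row=1, layer_scheme={"n/a": (1, 4)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_connectivity(rng: np.random.Generator, grid: GridSpec,
                        density: float) -> np.ndarray:
    """Random boolean site grid at a given connection density."""
    return rng.random(grid.shape) < density
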