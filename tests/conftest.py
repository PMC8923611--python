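import numpy as np
import pytest

from diffeoreg import Grid, ScalarField, VelocityField
from diffeoreg.synthetic import band_limited_velocity


@pytest.fixture
def grid16():
    return Grid((16, 16))


@pytest.fixture
def grid32():
    return Grid((32, 32))


@pytest.fixture
def grid64():
    return Grid((64, 64))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_scalar(grid: Grid, seed: int, max_mode: int = 2) -> ScalarField:
    """Seeded band-limited scalar field (resolvable on the grid)."""
    v = band_limited_velocity(grid, rng(seed), 1.0, max_mode=max_mode)
    return ScalarField(grid, v.data[0])


def random_velocity(
    grid: Grid, seed: int, magnitude: float = 1.0, max_mode: int = 2
) -> VelocityField:
    return band_limited_velocity(grid, rng(seed), magnitude, max_mode=max_mode)
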