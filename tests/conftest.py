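import numpy as np
import pytest

from pollinet import BinaryMap, GridSpec, SpeciesStack


@pytest.fixture
def small_grid():
    return GridSpec(n_rows=6, n_cols=8, origin_lat=10.0, origin_lon=20.0, cell_size=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(guild, arrays, grid, prefix=None):
    """Build a SpeciesStack from a list of 2-D arrays."""
    prefix = prefix or guild
    layers = tuple(
        BinaryMap(species_id=f"{prefix}_{i:03d}", grid=grid, values=np.asarray(a, dtype=float))
        for i, a in enumerate(arrays)
    )
    return SpeciesStack(guild=guild, layers=layers, grid=grid)


@pytest.fixture
def random_stacks(small_grid, rng):
    """A pair of random binary guild stacks with a few missing cells."""
    def draw(n):
        arrays = []
        for _ in range(n):
            a = (rng.random(small_grid.shape) < 0.4).astype(float)
            arrays.append(a)
        return arrays

    plant_arrays = draw(4)
    pol_arrays = draw(5)
    plant_arrays[0][0, 0] = np.nan  # one missing cell to exercise the usable mask
    return (
        make_stack("plant", plant_arrays, small_grid),
        make_stack("pollinator", pol_arrays, small_grid),
    )
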