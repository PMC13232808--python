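import numpy as np
import pytest

from nichekit import EnvStack, GridSpec


def make_stack(values_by_name: dict, cell_size: float = 1000.0,
               origin=(0.0, 0.0), crs_id: str = "EPSG:32652",
               mask=None) -> EnvStack:
    """Stack from a dict of 2-D arrays, all-valid mask by default."""
    names = list(values_by_name)
    arrays = [np.asarray(values_by_name[n], dtype=float) for n in names]
    nr, nc = arrays[0].shape
    grid = GridSpec(nr, nc, cell_size, origin[0], origin[1], crs_id)
    if mask is None:
        mask = np.ones((nr, nc), dtype=bool)
    return EnvStack(grid, names, np.stack(arrays), np.asarray(mask, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_stack(rng):
    """Three independent 20x20 layers on a 1 km projected grid."""
    vals = {f"v{i}": rng.standard_normal((20, 20)) for i in range(1, 4)}
    return make_stack(vals)
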