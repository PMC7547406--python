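import numpy as np
import pytest

from ramzml import GridMapping, RamanMap


def f32(values):
    """Round values through float32 so binary round trips are exact."""
    return np.asarray(values, dtype=np.float32).astype(np.float64)


def make_map(width=2, height=2, n_channels=3, *, seed=0, sparse=False,
             step=(2.0, 2.0), origin=(0.0, 0.0)):
    """Random dense (or one-hole sparse) map with float32-exact values."""
    rng = np.random.default_rng(seed)
    axis = f32(np.sort(600.0 + np.cumsum(rng.uniform(0.5, 5.0, n_channels))))
    k = np.arange(width * height)
    pixels = np.column_stack([k % width + 1, k // width + 1])
    if sparse and len(pixels) > 1:
        pixels = pixels[:-1]
    intensities = f32(rng.uniform(0.0, 1000.0, (len(pixels), n_channels)))
    grid = GridMapping(origin_x=origin[0], origin_y=origin[1],
                       step_x=step[0], step_y=step[1],
                       width=width, height=height)
    return RamanMap(axis=axis, pixels=pixels, intensities=intensities,
                    grid=grid, source_dialect="synthetic")


@pytest.fixture
def tiny_map():
    """2x2 dense map, 3 channels."""
    return make_map()


@pytest.fixture
def sparse_map():
    """2x2 grid with one empty cell."""
    return make_map(sparse=True)
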