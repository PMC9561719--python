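import numpy as np
import pytest

from firerange import GridRaster, make_grid


@pytest.fixture
def small_spec():
    """4x4 grid over a 1-degree box with unit cell area."""
    return make_grid((0.0, 0.0, 1.0, 1.0), 0.25, cell_area=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


def random_occurrence(spec, rng, p=0.3):
    return GridRaster(spec, (rng.random(spec.shape) < p).astype(float), "occurrence")


def random_mask(spec, rng, p=0.5):
    return GridRaster(spec, (rng.random(spec.shape) < p).astype(float), "mask")
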