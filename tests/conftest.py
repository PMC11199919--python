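"""Shared fixtures: small rasters, SWD tables, and synthetic study data."""

import numpy as np
import pytest

from hsm.raster import RasterStack

from helpers import make_study, make_swd


@pytest.fixture
def small_stack():
    """Two 10x10 layers on a mask with 60 valid cells, 50 m cells."""
    rng = np.random.default_rng(0)
    mask = np.zeros((10, 10), dtype=bool)
    mask.ravel()[rng.choice(100, 60, replace=False)] = True
    grid = np.stack([rng.normal(size=(10, 10)), rng.normal(size=(10, 10))])
    return RasterStack(
        names=["elev", "cover"],
        grid=grid,
        mask=mask,
        cell_size=50.0,
        origin=(0.0, 500.0),
    )


@pytest.fixture
def simple_swd():
    return make_swd()


@pytest.fixture(scope="session")
def study():
    return make_study(seed=0)
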