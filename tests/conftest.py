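import numpy as np
import pytest

from coxdeform.geometry import (Region, build_grid, discretize, PointPattern)
from coxdeform.inference import fit
from coxdeform.model import default_config

UNIT = Region(0.0, 1.0, 0.0, 1.0)


@pytest.fixture(scope="session")
def unit_region():
    return UNIT


@pytest.fixture(scope="session")
def grid4():
    return build_grid(UNIT, 4, 4)


@pytest.fixture(scope="session")
def counts4(grid4):
    """60 uniform events on the unit square, discretized on a 4x4 grid."""
    rng = np.random.default_rng(7)
    pattern = PointPattern(rng.uniform(0, 1, size=(60, 2)), UNIT)
    return discretize(pattern, grid4)


@pytest.fixture(scope="session")
def deformation_draws():
    """A small but genuine deformation-mode posterior fit (3x3 grid)."""
    grid = build_grid(UNIT, 3, 3)
    rng = np.random.default_rng(11)
    pattern = PointPattern(rng.uniform(0, 1, size=(80, 2)), UNIT)
    counts = discretize(pattern, grid)
    cfg = default_config(grid, counts.total, link="probit",
                         mode="deformation")
    return fit(counts, cfg, seed=21, chains=2, iters=160, warmup=80)
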