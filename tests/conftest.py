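import warnings

import numpy as np
import pytest

from ipsexp.grid import GridSpec
from ipsexp import synthgen
from ipsexp.synthgen import NicheSpec
from ipsexp.sdm import cross_validate


@pytest.fixture
def grid_small() -> GridSpec:
    return GridSpec(20, 30, cell_size=0.5, origin_lon=0.0, origin_lat=30.0)


@pytest.fixture
def stack_small(grid_small):
    return synthgen.generate_climate(grid_small, seed=7)


@pytest.fixture(scope="session")
def strong_world():
    """A larger world with a sharply separable species; shared by the SDM
    and evaluation suites (session-scoped: the CV fit is the expensive bit)."""
    grid = GridSpec(100, 150, cell_size=1.0 / 6.0, origin_lat=30.0)
    stack = synthgen.generate_climate(grid, seed=7)
    niche = NicheSpec(
        "sp001",
        "herb",
        optimum={"Bio1": 14.0, "Bio4": 600.0},
        breadth={"Bio1": 0.4, "Bio4": 15.0},
    )
    occ = synthgen.sample_occurrences(niche, stack, n_clean=150, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = cross_validate(occ, stack, k=4, seed=0, n_background=3000, n_knots=4)
    return {"grid": grid, "stack": stack, "niche": niche, "occ": occ, "cv": cv}
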