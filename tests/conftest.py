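import numpy as np
import pytest

import nichecast as nc
from nichecast.grid import ClimateStack, Grid, PointSet


@pytest.fixture(scope="session")
def default_landscape():
    """The default study landscape: 100x100 cells, 11 correlated layers."""
    spec = nc.LandscapeSpec(seed=1)
    return spec, nc.generate_climate_stack(spec)


@pytest.fixture(scope="session")
def uniform_background(default_landscape):
    """A landscape-representative background (2000 uniformly drawn cells),
    appropriate when occurrence sampling is unbiased."""
    _, stack = default_landscape
    rng = np.random.default_rng(7)
    idx = rng.choice(stack.grid.n_cells, 2000, replace=False)
    rows, cols = np.divmod(idx, stack.grid.n_cols)
    return PointSet(stack.grid, rows, cols, species="background")


@pytest.fixture(scope="session")
def community(default_landscape):
    """Five virtual species with 200 unbiased presences each."""
    spec, stack = default_landscape
    species = nc.make_virtual_species(5, spec, seed=2)
    occurrences = [
        nc.sample_occurrences(sp, stack, 200, seed=10 + i, for_modelling=True)
        for i, sp in enumerate(species)
    ]
    return species, occurrences


@pytest.fixture(scope="session")
def fitted_models(default_landscape, uniform_background, community):
    """Auto-feature fits of the five community species."""
    _, stack = default_landscape
    species, occurrences = community
    return [
        nc.fit_species(occ, uniform_background, stack)
        for occ in occurrences
    ]


@pytest.fixture
def tiny_stack():
    """A 5x8 two-layer stack for fast exactness tests."""
    rng = np.random.default_rng(0)
    grid = Grid(5, 8)
    return ClimateStack(grid, rng.normal(size=(2, 5, 8)), ["a", "b"])


def point_set(grid, flat_indices, species="pts", **kw):
    rows, cols = np.divmod(np.asarray(flat_indices, dtype=int), grid.n_cols)
    return PointSet(grid, rows, cols, species=species, **kw)


@pytest.fixture
def tiny_sets(tiny_stack):
    rng = np.random.default_rng(0)
    bg = point_set(tiny_stack.grid, rng.choice(40, 30, replace=False), "bg")
    pres = point_set(tiny_stack.grid, rng.choice(40, 12, replace=False), "sp")
    return pres, bg
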