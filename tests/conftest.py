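"""Shared fixtures: small grids and hand-built colony states."""

import numpy as np
import pytest

from wormcolony import FoodGrid, Genotype, make_gaussian_patch
from wormcolony.engine import ColonyState, Stage


@pytest.fixture
def genotype():
    """A mid-range genotype: day-1-only brood of 4, moderate aging."""
    return Genotype(F1=4, F2=4.0, M2=0.9, s_fed=0.3)


@pytest.fixture
def small_patch():
    """A 40 x 40 patch with 20,000 food units, enough for a small colony."""
    return make_gaussian_patch(40, 40, 2e4, sigma=3.0)


@pytest.fixture
def rich_grid():
    """A 30 x 30 grid with effectively unlimited food in every cell."""
    return FoodGrid(np.full((30, 30), 1e9))


def build_state(genotype, grid, individuals, seed=0):
    """ColonyState holding the given individuals.

    ``individuals`` is a list of dicts with keys stage, x, y and optional
    fed, starve_days, adult_age.
    """
    state = ColonyState(genotype, grid, seed=seed)
    for spec in individuals:
        state.add_individuals(1, spec["stage"], spec.get("x", grid.width // 2),
                              spec.get("y", grid.height // 2), founders=True)
        state.fed[-1] = spec.get("fed", False)
        state.starve_days[-1] = spec.get("starve_days", 0)
        state.adult_age[-1] = spec.get("adult_age", 0)
    return state


@pytest.fixture
def make_state():
    return build_state
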