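"""Shared fixtures: worked micro-examples and small synthetic datasets."""

import pytest

from cycadrisk import OccurrenceMatrix, parse_newick
from cycadrisk.simulate import SimConfig, simulate_dataset


@pytest.fixture
def toy_tree():
    """The worked 3-tip example: ((A:1,B:1):1,C:2); total length 5."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_occ():
    """A in cells 1,2; B in 1; C in 2,3."""
    return OccurrenceMatrix.from_records(
        [("A", 1), ("A", 2), ("B", 1), ("C", 2), ("C", 3)],
        grid_width=4, grid_height=1,
    )


@pytest.fixture(scope="session")
def small_config():
    """A fast cycad-like study: 60 species in 6 genera."""
    return SimConfig(seed=7, n_species=60, n_genera=6, grid_width=20, grid_height=10)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def full_config():
    """The default study conditions: 339 species, 11 genera."""
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def full_dataset(full_config):
    return simulate_dataset(full_config)
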