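"""Shared fixtures: small, deterministic synthetic datasets."""

import pytest

from imprintscan import simulate


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down validation design for fast unit tests."""
    return simulate.SimulationSpec(
        n_individuals=800, n_loci=60, n_additive=12, n_dominance=6,
        n_imprinting=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_validation(small_spec):
    return simulate.make_validation_dataset(small_spec)


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return simulate.make_validation_pair(small_spec)


@pytest.fixture(scope="session")
def mouse_spec():
    return simulate.FamilySpec(
        n_families=30, sibs_per_family=8, n_loci=60, n_cages=48, seed=5,
    )


@pytest.fixture(scope="session")
def mouse_data(mouse_spec):
    return simulate.make_mouse_like(mouse_spec)
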