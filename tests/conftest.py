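import numpy as np
import pytest

from actinet import (
    AtomSet,
    FilamentGraph,
    SynthParams,
    build_graph,
    generate_synthetic_filament,
)


def make_atoms(coords, bonds=(), elements=None):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if elements is None:
        elements = ["C"] * n
    return AtomSet(np.arange(n), np.array(elements), coords, list(bonds))


def make_graph(coords, bonds=(), rho=10.0):
    return build_graph(make_atoms(coords, bonds), None, rho)


def hand_graph(n, hard_pairs, soft_pairs, coords=None, rho=10.0):
    """Graph with explicitly prescribed neighbourhoods (coords only used
    for activity profiles)."""
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    return FilamentGraph(
        np.asarray(coords, dtype=float),
        np.array(hard_pairs, dtype=np.int64).reshape(-1, 2),
        np.array(soft_pairs, dtype=np.int64).reshape(-1, 2),
        rho,
    )


SMALL_PARAMS = SynthParams(n_monomers=4, atoms_per_monomer=60, seed=7)


@pytest.fixture(scope="session")
def small_filament():
    atoms = generate_synthetic_filament(SMALL_PARAMS)
    return atoms, build_graph(atoms, atoms.bonds, 10.0)


@pytest.fixture(scope="session")
def default_filament():
    atoms = generate_synthetic_filament(SynthParams())
    return atoms, build_graph(atoms, atoms.bonds, 10.0)
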