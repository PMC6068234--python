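import numpy as np
import pytest

from tvp.structure import AtomRecord, Structure
from tvp.synthetic import BundleSpec, make_bundle_structure


def structure_from_coords(coords, chain_id="A", start=1, resname="ALA"):
    atoms = [
        AtomRecord(i + 1, "CA", resname, chain_id, start + i,
                   tuple(float(c) for c in xyz))
        for i, xyz in enumerate(np.asarray(coords, dtype=float))
    ]
    return Structure(atoms)


@pytest.fixture(scope="session")
def small_bundle():
    """4-helix toy bundle (32 residues), enough geometry for every stage."""
    return make_bundle_structure(
        BundleSpec(n_helices=4, residues_per_helix=8, ring_radius=10.0, seed=7)
    )


@pytest.fixture(scope="session")
def medium_bundle():
    """8x10 bundle used where permutation nulls need head room."""
    return make_bundle_structure(
        BundleSpec(n_helices=8, residues_per_helix=10, ring_radius=14.0, seed=11)
    )


@pytest.fixture(scope="session")
def toy6():
    """Six residues where only residues 1 and 2 are within 15 Å of each other."""
    coords = [
        (0.0, 0.0, 0.0),
        (10.0, 0.0, 0.0),
        (100.0, 0.0, 0.0),
        (200.0, 0.0, 0.0),
        (0.0, 100.0, 0.0),
        (0.0, 200.0, 0.0),
    ]
    return structure_from_coords(coords)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
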