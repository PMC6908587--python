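"""Shared fixtures: synthetic chains, pockets and tetramers.

Everything is generated programmatically; no coordinate downloads are
needed for the unit/property suite.
"""
import numpy as np
import pytest

from hbstate.structure import Structure, write_pdb
from hbstate.synthetic import (HelixSpec, PocketSpec, TetramerSpec,
                               make_extended_strand, make_ideal_helix,
                               make_pocket, make_toy_tetramer)


@pytest.fixture(scope="session")
def alpha_helix_chain():
    return make_ideal_helix(HelixSpec(30, "alpha"))


@pytest.fixture(scope="session")
def three_ten_chain():
    return make_ideal_helix(HelixSpec(30, "three_ten"))


@pytest.fixture(scope="session")
def strand_chain():
    return make_extended_strand(12)


@pytest.fixture()
def pocket_structure():
    return make_pocket(PocketSpec(fe_ne2_distance=4.4, fe_out_of_plane=0.0,
                                  chi1=-60.0))


@pytest.fixture()
def toy_tetramer():
    return make_toy_tetramer(TetramerSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture()
def helix_pdb(tmp_path, alpha_helix_chain):
    path = tmp_path / "helix.pdb"
    write_pdb(Structure(structure_id="HLX", chains=[alpha_helix_chain]), path)
    return path
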