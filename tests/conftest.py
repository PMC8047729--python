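"""Shared fixtures: synthetic groove, its exemplar, and small libraries."""

import numpy as np
import pytest

from fibrilscreen.exemplar import ExemplarParams, build_exemplar
from fibrilscreen.synthetic import groove_structure, make_groove, make_library

GROOVE_SEED = 11


@pytest.fixture(scope="session")
def groove():
    """(pdb_text, manifest) for the default five-feature groove."""
    return make_groove(seed=GROOVE_SEED)


@pytest.fixture(scope="session")
def groove_struct(groove):
    pdb_text, _ = groove
    return groove_structure(pdb_text)


@pytest.fixture(scope="session")
def groove_manifest(groove):
    return groove[1]


@pytest.fixture(scope="session")
def groove_pocket_spec(groove_manifest):
    return groove_manifest.pocket_spec()


@pytest.fixture(scope="session")
def groove_exemplar(groove_struct, groove_pocket_spec):
    return build_exemplar(groove_struct, groove_pocket_spec, ExemplarParams())


@pytest.fixture(scope="session")
def active_sites(groove_manifest):
    """The groove's complementary ligand-feature sites."""
    return groove_manifest.complement_sites()


@pytest.fixture(scope="session")
def small_library(active_sites):
    """Planted active plus 30 structured decoys."""
    return make_library(seed=3, n_decoys=30, active_sites=active_sites)


def write_pdb(tmp_path, text, name="test.pdb"):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


def pdb_atom_line(serial, name, res, chain, resi, x, y, z, occ=1.0, element=None, alt=" "):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:<4s}{alt}{res:<3s} {chain}{resi:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def handcrafted_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 2.5, 2.0, 3.0, element="C"),
        pdb_atom_line(3, "C", "ALA", "A", 1, 3.5, 3.0, 3.0),
        "END",
    ]
    return write_pdb(tmp_path, "\n".join(lines) + "\n")


@pytest.fixture
def altloc_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.6, element="C", alt="A"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.4, element="C", alt="B"),
        pdb_atom_line(3, "N", "ALA", "A", 1, 1.0, 1.0, 0.0),
        "END",
    ]
    return write_pdb(tmp_path, "\n".join(lines) + "\n", name="altloc.pdb")


def rigid_motion(rng=None, angle_scale=1.0, trans_scale=5.0):
    """A random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    rng = rng or np.random.default_rng(0)
    rot = Rotation.random(random_state=rng).as_matrix()
    return rot, rng.normal(0.0, trans_scale, 3)
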