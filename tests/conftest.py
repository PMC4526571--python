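import numpy as np
import pytest

from pocketsim import (
    Atom,
    BindingSite,
    LigandPose,
    PocketSpec,
    Residue,
    extract_pocket,
    generate_pocket,
    pocket_ligand,
)


def make_residue(res_name, atom_spec, chain_id="A", res_seq=1):
    """Build a residue from [(name, element, (x, y, z)), ...]."""
    atoms = [Atom(name=n, element=e, coord=np.array(c, dtype=float)) for n, e, c in atom_spec]
    return Residue(res_name, chain_id, res_seq, atoms)


def gly_at(ca, res_seq=1, chain_id="A"):
    return make_residue(
        "GLY",
        [("N", "N", (ca[0] - 1.0, ca[1], ca[2])),
         ("CA", "C", tuple(ca)),
         ("C", "C", (ca[0] + 1.0, ca[1], ca[2])),
         ("O", "O", (ca[0] + 1.5, ca[1] + 1.0, ca[2]))],
        chain_id=chain_id,
        res_seq=res_seq,
    )


def dummy_ligand(center=(0.0, 0.0, 0.0)):
    return LigandPose(
        code="SBX",
        atoms=[Atom(name="C1", element="C", coord=np.array(center), is_hetero=True)],
    )


def two_gly_site(ca_distance, cutoff=10.0):
    """Two glycines separated by `ca_distance` along x; minimal PMScore input."""
    residues = [gly_at((0.0, 0.0, 0.0), res_seq=1), gly_at((ca_distance, 0.0, 0.0), res_seq=2)]
    return BindingSite(residues=residues, ligand=dummy_ligand(), cutoff=cutoff)


def site_from_structure(structure, cutoff=9.5, label=""):
    lig = pocket_ligand(structure)
    site = extract_pocket(structure, lig, cutoff)
    site.source_label = label
    return site


@pytest.fixture(scope="session")
def pocket_structure():
    return generate_pocket(PocketSpec(seed=7))


@pytest.fixture(scope="session")
def pocket_site(pocket_structure):
    return site_from_structure(pocket_structure, label="pocket7")
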