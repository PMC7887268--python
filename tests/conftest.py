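"""Shared fixtures: small synthetic structures built programmatically."""

import numpy as np
import pytest

from bzrmd.structure import AtomRecord, StructureModel
from bzrmd.synthetic import HelixSpec, make_helix_pair, make_ideal_helix


@pytest.fixture
def ideal_helix() -> StructureModel:
    return make_ideal_helix(HelixSpec(n_residues=12, chain_id="A"))


@pytest.fixture
def helix_pair_78() -> StructureModel:
    """Synthetic stand-in dimer at the BZR-like 78° crossing angle."""
    return make_helix_pair(
        HelixSpec(n_residues=12, chain_id="A"),
        HelixSpec(n_residues=12, chain_id="B"),
        crossing_angle=78.0,
    )


@pytest.fixture
def dna_strand() -> StructureModel:
    """Synthetic 15-nucleotide strand whose 5' residue lacks its phosphate.

    Geometry is schematic (6.5 Å rise per nucleotide); only atom identities
    matter for selection tests.
    """
    atoms = []
    serial = 0
    bases = ["DA", "DC", "DG", "DT", "DA"] * 3
    for i, base in enumerate(bases, start=1):
        z = 6.5 * i
        names = [("C1'", "C"), ("O4'", "O")]
        if i > 1:  # 5' overhang: first residue has no phosphate
            names = [("P", "P"), ("OP1", "O"), ("OP2", "O")] + names
        for name, element in names:
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, residue_name=base, chain_id="E",
                    residue_number=i,
                    coordinates=np.array([serial * 0.1, 0.0, z]),
                    element=element,
                )
            )
    return StructureModel(atoms=atoms, source_id="synthetic-dna-strand")


def make_polar_pair(distance: float, donor=("LYS", "NZ", "N"), acceptor=("GLU", "OE1", "O"),
                    chain_a="A", chain_b="B") -> StructureModel:
    """Two-atom model: a donor and an acceptor ``distance`` Å apart."""
    d_res, d_name, d_el = donor
    a_res, a_name, a_el = acceptor
    atoms = [
        AtomRecord(serial=1, name=d_name, residue_name=d_res, chain_id=chain_a,
                   residue_number=1, coordinates=np.zeros(3), element=d_el),
        AtomRecord(serial=2, name=a_name, residue_name=a_res, chain_id=chain_b,
                   residue_number=1, coordinates=np.array([distance, 0.0, 0.0]),
                   element=a_el),
    ]
    return StructureModel(atoms=atoms, source_id="synthetic-polar-pair")
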