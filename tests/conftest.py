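import numpy as np
import pytest

from thermolegacy.rigidity import Atom, Structure


def _atom(serial, name, element, res_name, res_id, x, y, z, chain="A"):
    return Atom(serial=serial, name=name, element=element, res_name=res_name,
                res_id=res_id, chain=chain, coord=(x, y, z))


@pytest.fixture
def diatomic_structure():
    """Two bonded carbons; a single rotatable covalent bar."""
    atoms = (
        _atom(1, "C1", "C", "LIG", 1, 0.0, 0.0, 0.0),
        _atom(2, "C2", "C", "LIG", 1, 1.5, 0.0, 0.0),
    )
    return Structure(atoms=atoms, bonds=((0, 1, 1),))


@pytest.fixture
def hbond_structure():
    """One ideal N-H...O=C hydrogen bond (theta = 180 deg, phi = 120 deg,
    H...A = 1.9 A, D...A = 2.9 A) plus one acceptor far beyond the screens."""
    atoms = (
        _atom(1, "N", "N", "GLY", 1, 0.0, 0.0, 0.0),
        _atom(2, "H", "H", "GLY", 1, 1.0, 0.0, 0.0),
        _atom(3, "O", "O", "GLY", 2, 2.9, 0.0, 0.0),
        _atom(4, "C", "C", "GLY", 2, 3.515, 1.065, 0.0),
        _atom(5, "OXT", "O", "GLY", 3, 8.0, 0.0, 0.0),
        _atom(6, "CB", "C", "GLY", 3, 1.7, 2.5, 0.0),
    )
    # single covalent component: CB bridges the donor and acceptor groups
    bonds = ((0, 1, 1), (2, 3, 2), (0, 5, 1), (3, 5, 1), (4, 5, 1))
    return Structure(atoms=atoms, bonds=bonds)


@pytest.fixture
def dipeptide_structure():
    """Two-residue backbone with explicit bonds for bar-type counting:
    3 locked bars (two C=O, one peptide C-N) and 5 rotatable bars; exactly
    one nonbonded C...C pair within tether range (C1-CA2, 2.9 A)."""
    atoms = (
        _atom(1, "N", "N", "GLY", 1, 0.0, 0.0, 0.0),
        _atom(2, "CA", "C", "GLY", 1, 1.5, 0.0, 0.0),
        _atom(3, "C", "C", "GLY", 1, 3.0, 0.0, 0.0),
        _atom(4, "O", "O", "GLY", 1, 3.0, 1.2, 0.0),
        _atom(5, "N", "N", "GLY", 2, 4.4, 0.0, 0.0),
        _atom(6, "H", "H", "GLY", 2, 4.4, -1.5, 0.0),
        _atom(7, "CA", "C", "GLY", 2, 5.9, 0.0, 0.0),
        _atom(8, "C", "C", "GLY", 2, 7.4, 0.0, 0.0),
        _atom(9, "O", "O", "GLY", 2, 7.4, 1.2, 0.0),
    )
    bonds = ((0, 1, 1), (1, 2, 1), (2, 3, 2), (2, 4, 1),
             (4, 5, 1), (4, 6, 1), (6, 7, 1), (7, 8, 2))
    return Structure(atoms=atoms, bonds=bonds)


def format_pdb_line(serial, name, res_name, chain, res_id, x, y, z,
                    element, record="ATOM", altloc=" "):
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{res_name:>3} "
            f"{chain}{res_id:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2}")


@pytest.fixture
def pdb_text():
    lines = [
        format_pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        format_pdb_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0, "C"),
        format_pdb_line(3, "C", "ALA", "A", 1, 2.0, 1.42, 0.0, "C"),
        format_pdb_line(4, "O", "ALA", "A", 1, 1.25, 2.39, 0.0, "O"),
        format_pdb_line(5, "CB", "ALA", "A", 1, 2.0, -0.77, 1.2, "C"),
        format_pdb_line(6, "O", "HOH", "A", 2, 9.0, 9.0, 9.0, "O",
                        record="HETATM"),
        "END",
    ]
    return "\n".join(lines) + "\n"
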