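"""Minimal protonated-structure model used by the network builder."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: single-bond covalent radii (angstrom) for bond inference
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "MG": 1.41,
    "K": 2.03, "CA": 1.76, "FE": 1.32, "ZN": 1.22, "MN": 1.39, "SE": 1.20,
}

VDW_RADII = {"C": 1.70, "S": 1.80}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_id: int          # 1-based as in the source file
    chain: str
    coord: tuple[float, float, float]
    altloc: str = ""


@dataclass(frozen=True)
class Structure:
    atoms: tuple[Atom, ...]
    # optional explicit bonds: (atom index, atom index, bond order)
    bonds: tuple[tuple[int, int, int], ...] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for a in self.atoms:
            if not all(np.isfinite(c) for c in a.coord):
                raise ValueError(f"non-finite coordinates on atom {a.serial}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def has_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)


def infer_bonds(structure: Structure,
                tolerance: float = 0.4) -> tuple[tuple[int, int, int], ...]:
    """Distance-based covalent bond inference: a pair is bonded when closer
    than the sum of covalent radii plus ``tolerance``.  Returned bond orders
    are all 1; callers refine locked/rotatable classification separately."""
    from scipy.spatial import cKDTree

    xyz = structure.coords
    radii = np.array([COVALENT_RADII.get(a.element, 0.77)
                      for a in structure.atoms])
    tree = cKDTree(xyz)
    max_cut = 2 * radii.max() + tolerance
    bonds = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if 0.4 < d <= radii[i] + radii[j] + tolerance:
            if structure.atoms[i].element == "H" and \
                    structure.atoms[j].element == "H":
                continue
            bonds.append((i, j, 1))
    return tuple(bonds)
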