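"""Hydrogen-bond detection, salt bridges, and the Mayo-form energy function.

Energy model:

    E = V0 * (5 (R0/R)^12 - 6 (R0/R)^10) * F(angles),   V0 = 8 kcal/mol,
    R0 = 2.8 A (donor-acceptor distance)

with an angular factor built from the D-H...A angle theta and the H...A-AA
angle phi at the acceptor; the phi term centres on the tetrahedral angle for
sp3 acceptors and 120 degrees for sp2 acceptors.  F is 1 at ideal geometry
(theta = 180 degrees, phi ideal), so a bond at R = R0 scores -V0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, VDW_RADII, infer_bonds

MAYO_V0 = 8.0       # kcal/mol
MAYO_R0 = 2.8       # angstrom

# default geometric screens
MAX_HA = 2.6        # H...A distance
MAX_DA = 3.6        # D...A distance
MIN_DHA_DEG = 90.0

SALT_BRIDGE_CUTOFF = 4.0
_POSITIVE = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
             ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}
_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

IDEAL_PHI = {"sp3": np.deg2rad(109.5), "sp2": np.deg2rad(120.0)}


@dataclass(frozen=True)
class HBondGeometry:
    donor: int          # heavy-atom index
    hydrogen: int
    acceptor: int
    r_da: float
    r_ha: float
    theta_dha: float    # radians
    phi_haa: float | None   # radians; None when the acceptor has no neighbour
    donor_hyb: str      # sp2 | sp3
    acceptor_hyb: str


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, in radians."""
    v1, v2 = a - b, c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


def _hybridisation(structure: Structure, idx: int,
                   neighbours: list[int]) -> str:
    """Crude sp2/sp3 assignment: carbonyl-like O (single heavy neighbour,
    no H) and amide/aromatic N (>= 2 heavy neighbours, part of a planar
    group) read as sp2; hydroxyls, waters and amines as sp3."""
    atom = structure.atoms[idx]
    heavy = [n for n in neighbours if structure.atoms[n].element != "H"]
    hydro = [n for n in neighbours if structure.atoms[n].element == "H"]
    if atom.element == "O":
        return "sp2" if len(heavy) == 1 and not hydro else "sp3"
    if atom.element == "N":
        return "sp2" if len(heavy) >= 2 or atom.name in ("N",) else "sp3"
    return "sp3"


def _adjacency(structure: Structure,
               bonds) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(structure.n_atoms)]
    for i, j, _order in bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def detect_hbonds(structure: Structure, bonds=None, *,
                  max_ha: float = MAX_HA, max_da: float = MAX_DA,
                  min_dha_deg: float = MIN_DHA_DEG) -> list[HBondGeometry]:
    """Donor-H...acceptor triples passing the geometric screens.

    Donors are N/O/S atoms with a bonded hydrogen; acceptors are N/O/S
    atoms.  Raises when the structure carries no hydrogens (inputs must be
    protonated upstream).
    """
    if not structure.has_hydrogens():
        raise ValueError("structure has no hydrogens; protonate the input "
                         "before hydrogen-bond detection")
    if bonds is None:
        bonds = structure.bonds or infer_bonds(structure)
    adj = _adjacency(structure, bonds)
    xyz = structure.coords
    min_dha = np.deg2rad(min_dha_deg)

    acceptors = [i for i, a in enumerate(structure.atoms)
                 if a.element in ("N", "O", "S")]
    out: list[HBondGeometry] = []
    for h, atom in enumerate(structure.atoms):
        if atom.element != "H":
            continue
        donors = [n for n in adj[h]
                  if structure.atoms[n].element in ("N", "O", "S")]
        if not donors:
            continue
        d = donors[0]
        for a in acceptors:
            if a == d or a == h or a in adj[d]:
                continue
            r_ha = float(np.linalg.norm(xyz[h] - xyz[a]))
            r_da = float(np.linalg.norm(xyz[d] - xyz[a]))
            if r_ha > max_ha or r_da > max_da:
                continue
            theta = _angle(xyz[d], xyz[h], xyz[a])
            if theta < min_dha:
                continue
            acc_heavy = [n for n in adj[a]
                         if structure.atoms[n].element != "H"]
            phi = _angle(xyz[h], xyz[a], xyz[acc_heavy[0]]) \
                if acc_heavy else None
            out.append(HBondGeometry(
                donor=d, hydrogen=h, acceptor=a, r_da=r_da, r_ha=r_ha,
                theta_dha=theta, phi_haa=phi,
                donor_hyb=_hybridisation(structure, d, adj[d]),
                acceptor_hyb=_hybridisation(structure, a, adj[a])))
    return out


def hbond_energy(geom: HBondGeometry, *, v0: float = MAYO_V0,
                 r0: float = MAYO_R0) -> float:
    """Mayo-form hydrogen-bond energy (kcal/mol) from a geometry triple."""
    if geom.r_da <= 0:
        raise ValueError("degenerate geometry: zero donor-acceptor distance")
    ratio = r0 / geom.r_da
    radial = v0 * (5.0 * ratio ** 12 - 6.0 * ratio ** 10)
    theta = geom.theta_dha
    ang = np.cos(theta) ** 2 * np.exp(-((np.pi - theta) ** 6))
    if geom.donor_hyb == "sp2" and geom.acceptor_hyb == "sp3":
        f = np.cos(theta) ** 4 * np.exp(-((np.pi - theta) ** 6))
    else:
        f = ang
        if geom.phi_haa is not None:
            ideal = IDEAL_PHI[geom.acceptor_hyb]
            f = f * np.cos(geom.phi_haa - ideal) ** 2
    return float(radial * f)


def detect_salt_bridges(structure: Structure, *,
                        cutoff: float = SALT_BRIDGE_CUTOFF
                        ) -> list[tuple[int, int, float]]:
    """Charged-group N/O pairs within ``cutoff``; returns (i, j, distance)."""
    pos = [i for i, a in enumerate(structure.atoms)
           if (a.res_name, a.name) in _POSITIVE]
    neg = [i for i, a in enumerate(structure.atoms)
           if (a.res_name, a.name) in _NEGATIVE]
    xyz = structure.coords
    out = []
    for i in pos:
        for j in neg:
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d <= cutoff:
                out.append((i, j, d))
    return out


def salt_bridge_energy(distance: float, *, v0: float = MAYO_V0,
                       r0: float = MAYO_R0) -> float:
    """Distance-only Mayo term (ideal angular factor) for salt bridges."""
    if distance <= 0:
        raise ValueError("degenerate geometry: zero distance")
    ratio = r0 / distance
    return float(v0 * (5.0 * ratio ** 12 - 6.0 * ratio ** 10))


def hydrophobic_pairs(structure: Structure, bonds, *,
                      cutoff: float = 3.5, radii_pad: float = 0.25
                      ) -> list[tuple[int, int]]:
    """Nonpolar C/S atom pairs close enough for a tether: not covalently
    bonded, within both the 3.5 A screen and the vdW-radii + pad criterion."""
    adj = _adjacency(structure, bonds)
    carbons = [i for i, a in enumerate(structure.atoms)
               if a.element in ("C", "S")]
    xyz = structure.coords
    out = []
    for ii, i in enumerate(carbons):
        for j in carbons[ii + 1:]:
            if j in adj[i]:
                continue
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            r_sum = VDW_RADII[structure.atoms[i].element] + \
                VDW_RADII[structure.atoms[j].element]
            if d <= min(cutoff, r_sum + radii_pad):
                out.append((i, j))
    return out
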