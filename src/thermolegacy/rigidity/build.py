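"""Constraint-network construction from a protonated structure."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .hbonds import (detect_hbonds, detect_salt_bridges, hbond_energy,
                     hydrophobic_pairs, salt_bridge_energy)
from .network import Bar, BarType, ConstraintNetwork
from .structure import Structure, infer_bonds


@dataclass(frozen=True)
class NetworkOptions:
    include_tethers: bool = True
    include_salt_bridges: bool = True
    max_ha: float = 2.6
    max_da: float = 3.6
    min_dha_deg: float = 90.0
    # "mayo" or a fixed kcal/mol value for salt-bridge bars
    salt_bridge_energy: str | float = "mayo"


def _locked(structure: Structure, i: int, j: int, order: int) -> bool:
    """Peptide bonds and multiple bonds are locked (6 bars)."""
    if order >= 2:
        return True
    a, b = structure.atoms[i], structure.atoms[j]
    pair = {a.name, b.name}
    if pair == {"C", "N"} and a.res_id != b.res_id:
        return True
    return False


def _largest_component(n: int, bonds) -> list[int]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n
    best: list[int] = []
    for start in range(n):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        if len(comp) > len(best):
            best = comp
    return sorted(best)


def build_network(structure: Structure,
                  options: NetworkOptions = NetworkOptions()
                  ) -> ConstraintNetwork:
    """Typed body-bar network: covalent bars from bonded topology, energy-
    annotated hydrogen-bond/salt-bridge bars, optional hydrophobic tethers.

    A disconnected covalent graph raises a warning and restricts the network
    to the largest component (atom indices kept in ``meta['atom_indices']``).
    """
    bonds = structure.bonds if structure.bonds is not None \
        else infer_bonds(structure)
    if not bonds:
        raise ValueError("structure has no covalent bonds")

    keep = _largest_component(structure.n_atoms, bonds)
    if len(keep) < structure.n_atoms:
        warnings.warn(
            f"covalent graph disconnected; analysing largest component "
            f"({len(keep)}/{structure.n_atoms} atoms)")
    remap = {atom: body for body, atom in enumerate(keep)}
    in_comp = set(keep)

    bars: list[Bar] = []
    for i, j, order in bonds:
        if i not in in_comp or j not in in_comp:
            continue
        btype = BarType.COVALENT_LOCKED if _locked(structure, i, j, order) \
            else BarType.COVALENT_ROTATABLE
        bars.append(Bar(remap[i], remap[j], btype))

    sb_pairs: set[frozenset[int]] = set()
    if options.include_salt_bridges:
        for i, j, dist in detect_salt_bridges(structure):
            if i not in in_comp or j not in in_comp:
                continue
            if options.salt_bridge_energy == "mayo":
                e = salt_bridge_energy(dist)
            else:
                e = float(options.salt_bridge_energy)
            if e <= 0:
                bars.append(Bar(remap[i], remap[j], BarType.SALTBRIDGE,
                                energy=e))
                sb_pairs.add(frozenset((i, j)))

    hbond_geoms = []
    if structure.has_hydrogens():
        hbond_geoms = detect_hbonds(structure, bonds, max_ha=options.max_ha,
                                    max_da=options.max_da,
                                    min_dha_deg=options.min_dha_deg)
    else:
        warnings.warn("structure has no hydrogens; hydrogen bonds skipped")
    for geom in hbond_geoms:
        if geom.donor not in in_comp or geom.acceptor not in in_comp:
            continue
        if frozenset((geom.donor, geom.acceptor)) in sb_pairs:
            continue
        e = hbond_energy(geom)
        if e <= 0:
            bars.append(Bar(remap[geom.donor], remap[geom.acceptor],
                            BarType.HBOND, energy=e))

    if options.include_tethers:
        for i, j in hydrophobic_pairs(structure, bonds):
            if i in in_comp and j in in_comp:
                bars.append(Bar(remap[i], remap[j], BarType.TETHER))

    return ConstraintNetwork(
        n_bodies=len(keep), bars=tuple(bars),
        meta={"atom_indices": keep, "n_atoms_input": structure.n_atoms})
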