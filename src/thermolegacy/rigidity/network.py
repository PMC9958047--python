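"""Constraint-network representation: bodies joined by typed, multi-bar edges.

Bar multiplicities follow the published body-bar conventions: rotatable
covalent bonds 5 bars, locked (peptide/double) bonds 6, hydrogen bonds and
salt bridges 5, hydrophobic tethers 2.  Hydrogen-bond class bars carry an
energy used by the dilution schedule; tethers and covalent bars are exempt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd


class BarType(str, Enum):
    COVALENT_ROTATABLE = "covalent-rotatable"
    COVALENT_LOCKED = "covalent-locked"
    HBOND = "hbond"
    SALTBRIDGE = "saltbridge"
    TETHER = "hydrophobic"


MULTIPLICITY = {
    BarType.COVALENT_ROTATABLE: 5,
    BarType.COVALENT_LOCKED: 6,
    BarType.HBOND: 5,
    BarType.SALTBRIDGE: 5,
    BarType.TETHER: 2,
}

#: bar classes removed by the thermal-unfolding schedule
DILUTABLE = (BarType.HBOND, BarType.SALTBRIDGE)


@dataclass(frozen=True)
class Bar:
    i: int
    j: int
    type: BarType
    energy: float | None = None     # kcal/mol, hbond/saltbridge only

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-bars are not allowed")
        if self.type in DILUTABLE:
            if self.energy is None or not (self.energy == self.energy):
                raise ValueError(f"{self.type.value} bar needs a finite energy")
            if self.energy > 0:
                raise ValueError("favourable bond energies must be <= 0")

    @property
    def multiplicity(self) -> int:
        return MULTIPLICITY[self.type]


@dataclass(frozen=True)
class ConstraintNetwork:
    n_bodies: int
    bars: tuple[Bar, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.n_bodies < 1:
            raise ValueError("need at least one body")
        for b in self.bars:
            if not (0 <= b.i < self.n_bodies and 0 <= b.j < self.n_bodies):
                raise ValueError("bar endpoint out of range")

    def bars_present(self, e_cut: float | None = None) -> tuple[Bar, ...]:
        """Bars surviving a cutoff: dilutable bars with energy > e_cut are
        removed; with ``e_cut=None`` everything is present."""
        if e_cut is None:
            return self.bars
        return tuple(b for b in self.bars
                     if b.type not in DILUTABLE or b.energy <= e_cut)

    def canonical_bars(self, e_cut: float | None = None) -> list[Bar]:
        return sorted(self.bars_present(e_cut),
                      key=lambda b: (min(b.i, b.j), max(b.i, b.j),
                                     b.type.value, b.energy or 0.0))

    # -- serialisation ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"i": b.i, "j": b.j, "type": b.type.value,
             "multiplicity": b.multiplicity, "energy": b.energy}
            for b in self.bars
        ])

    def to_json(self) -> str:
        return json.dumps({
            "n_bodies": self.n_bodies,
            "bars": [[b.i, b.j, b.type.value, b.energy] for b in self.bars],
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, list, tuple))},
        })

    @classmethod
    def from_json(cls, text: str) -> "ConstraintNetwork":
        d = json.loads(text)
        bars = tuple(Bar(i, j, BarType(t), e) for i, j, t, e in d["bars"])
        return cls(n_bodies=d["n_bodies"], bars=bars, meta=d.get("meta", {}))
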