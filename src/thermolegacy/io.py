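"""File formats and configuration: PDB subset reader, CSV/JSON round-trips,
and the pipeline configuration object.

CSV dialect everywhere: UTF-8, comma-separated, header row, '.' decimal.
Temperatures are degC in user-facing files; rigidity trajectories emit both
the cutoff and the mapped kelvin column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .rigidity.structure import Atom, Structure

_WATER_RES = {"HOH", "WAT", "DOD", "H2O"}


def read_pdb(path, *, keep_waters: bool = False,
             altloc: str = "A") -> Structure:
    """Parse the ATOM/HETATM subset of a PDB file.

    Keeps blank or ``altloc`` alternate locations, drops waters by default,
    preserves 1-based residue numbering.  Malformed records raise with the
    offending line number.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                alt = line[16].strip()
                res_name = line[17:20].strip()
                chain = line[21].strip()
                res_id = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip().upper()
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed {rec} record: "
                    f"{exc}") from exc
            if alt and alt != altloc:
                continue
            if not keep_waters and res_name in _WATER_RES:
                continue
            if not element:
                element = "".join(c for c in name if c.isalpha())[:1].upper()
            atoms.append(Atom(serial=serial, name=name, element=element,
                              res_name=res_name, res_id=res_id, chain=chain,
                              coord=(x, y, z), altloc=alt))
    if not atoms:
        raise ValueError(f"{path.name}: no usable ATOM/HETATM records "
                         "(empty file or waters only)")
    return Structure(atoms=tuple(atoms), meta={"source": str(path)})


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_csv(frame: pd.DataFrame, path, *, header_comment: str | None = None
              ) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_sites: int = 120
    relation: str = "piecewise"
    intercept: float = 12.0
    slope_before: float = 0.45
    slope_after: float = 6.48
    breakpoint: float = 27.7
    site_noise_sd: float = 0.5
    assay_noise_sd: float = 0.001
    melt_noise_frac: float = 0.01
    # assay constants
    epsilon: float = 4147.0
    path_cm: float = 0.4
    volume_l: float = 0.0002
    protein_mg: float = 0.001
    assay_temperatures: tuple[float, ...] = tuple(range(4, 82, 2))
    assay_duration_min: float = 40.0
    assay_interval_s: float = 120.0
    # thresholds
    od_threshold: float = 0.15
    td_rule_c: float = 50.0
    variability_bins: tuple[float, float] = (28.0, 31.0)
    # dilution schedule (start > stop, decreasing)
    schedule_start: float = -0.1
    schedule_stop: float = -6.0
    schedule_step: float = -0.1
    rigidity_planted_ecuts: tuple[float, ...] = (-1.0, -2.0, -3.0, -4.0, -5.0)
    rigidity_n_bodies: int = 12
    logger_months: int = 18
    growth_temperatures: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)

    def __post_init__(self):
        if self.schedule_start <= self.schedule_stop:
            raise ValueError("schedule must decrease (start > stop)")
        for name in ("od_threshold", "td_rule_c", "epsilon", "path_cm",
                     "volume_l", "protein_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("assay_temperatures", "variability_bins",
                    "rigidity_planted_ecuts", "growth_temperatures"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
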