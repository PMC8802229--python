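"""Multi-model coordinate ensembles in mmCIF (PDBx) format.

Reading is backed by Biopython's ``MMCIF2Dict`` (tolerant tag/loop
parsing); model separation, altloc resolution and the polymer flag are
handled here.  Writing emits a standard ``_atom_site`` category with
model numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB.MMCIF2Dict import MMCIF2Dict

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureFormatError(ValueError):
    """Raised when a coordinate file lacks an atom-site category."""


@dataclass(frozen=True)
class AtomSite:
    """One atom in one model; coordinates in Angstrom."""

    chain_id: str
    seq_id: int
    residue_type: str
    atom_name: str
    x: float
    y: float
    z: float
    is_polymer: bool = True

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for {self.atom_name}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def atom_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.atom_name)


@dataclass
class Model:
    number: int
    atoms: dict[tuple[str, int, str], AtomSite] = field(default_factory=dict)

    def add(self, site: AtomSite) -> None:
        self.atoms[site.atom_key] = site

    def roster(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(self.atoms)


@dataclass
class Ensemble:
    """Ordered multi-model coordinate set for one entry."""

    entry_id: str
    models: list[Model] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def model_numbers(self) -> list[int]:
        return [m.number for m in self.models]

    def common_roster(self) -> frozenset[tuple[str, int, str]]:
        """Atom keys present in every model; warns if rosters differ."""
        if not self.models:
            return frozenset()
        rosters = [m.roster() for m in self.models]
        common = frozenset.intersection(*rosters)
        if any(r != common for r in rosters):
            logger.warning(
                "%s: atom rosters differ across models; using intersection (%d atoms)",
                self.entry_id,
                len(common),
            )
        return common

    def residue_types(self) -> dict[tuple[str, int], str]:
        """(chain, seq) -> residue type, from the first model defining each."""
        out: dict[tuple[str, int], str] = {}
        for model in self.models:
            for site in model.atoms.values():
                out.setdefault((site.chain_id, site.seq_id), site.residue_type)
        return out


def _column(d: dict, *names: str) -> list[str] | None:
    for name in names:
        if name in d:
            val = d[name]
            return val if isinstance(val, list) else [val]
    return None


def read_ensemble(path: str | Path) -> Ensemble:
    """Load every model's atoms; non-polymer sites loaded but flagged.

    Altlocs resolve to the highest-occupancy conformer (tie: first seen).
    Chain identity comes from the author chain field when present, else
    the label field.
    """
    path = Path(path)
    d = MMCIF2Dict(str(path))
    xs = _column(d, "_atom_site.Cartn_x")
    if xs is None:
        raise StructureFormatError(f"no _atom_site category in {path}")
    n = len(xs)
    ys = _column(d, "_atom_site.Cartn_y")
    zs = _column(d, "_atom_site.Cartn_z")
    group = _column(d, "_atom_site.group_PDB") or ["ATOM"] * n
    atom_ids = _column(d, "_atom_site.auth_atom_id", "_atom_site.label_atom_id")
    comp_ids = _column(d, "_atom_site.auth_comp_id", "_atom_site.label_comp_id")
    chain_ids = _column(d, "_atom_site.auth_asym_id", "_atom_site.label_asym_id")
    seq_ids = _column(d, "_atom_site.auth_seq_id", "_atom_site.label_seq_id")
    models = _column(d, "_atom_site.pdbx_PDB_model_num") or ["1"] * n
    altloc = _column(d, "_atom_site.label_alt_id") or ["."] * n
    occ = _column(d, "_atom_site.occupancy") or ["1.0"] * n

    entry_id = None
    for key in ("_entry.id", "data_"):
        if key in d:
            val = d[key]
            entry_id = val[0] if isinstance(val, list) else val
            break
    entry_id = entry_id or path.stem

    by_model: dict[int, Model] = {}
    best_occ: dict[tuple[int, str, int, str], float] = {}
    for i in range(n):
        comp = comp_ids[i].upper()
        mnum = int(models[i])
        model = by_model.setdefault(mnum, Model(number=mnum))
        try:
            seq = int(seq_ids[i])
        except ValueError:
            continue  # non-polymer rows with '.' seq ids are unaddressable
        site = AtomSite(
            chain_id=chain_ids[i],
            seq_id=seq,
            residue_type=comp,
            atom_name=atom_ids[i],
            x=float(xs[i]),
            y=float(ys[i]),
            z=float(zs[i]),
            is_polymer=group[i] == "ATOM" and comp not in _WATER_NAMES,
        )
        key = (mnum, *site.atom_key)
        if altloc[i] not in (".", "?"):
            o = float(occ[i]) if occ[i] not in (".", "?") else 1.0
            if key in best_occ and o <= best_occ[key]:
                continue
            best_occ[key] = o
        elif key in best_occ:
            continue
        model.add(site)
    ensemble = Ensemble(entry_id=entry_id, models=[by_model[k] for k in sorted(by_model)])
    return ensemble


_ATOM_SITE_TAGS = [
    "_atom_site.group_PDB",
    "_atom_site.id",
    "_atom_site.type_symbol",
    "_atom_site.label_atom_id",
    "_atom_site.label_comp_id",
    "_atom_site.label_asym_id",
    "_atom_site.label_seq_id",
    "_atom_site.Cartn_x",
    "_atom_site.Cartn_y",
    "_atom_site.Cartn_z",
    "_atom_site.occupancy",
    "_atom_site.B_iso_or_equiv",
    "_atom_site.auth_seq_id",
    "_atom_site.auth_comp_id",
    "_atom_site.auth_asym_id",
    "_atom_site.auth_atom_id",
    "_atom_site.pdbx_PDB_model_num",
]


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper() if ch.upper() in "HCNOSP" else "C"
    return "C"


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write a PDBx atom-site category, coordinates to 3 decimals."""
    path = Path(path)
    lines = [f"data_{ensemble.entry_id}", "#", "loop_"]
    lines += _ATOM_SITE_TAGS
    serial = 0
    for model in ensemble.models:
        for site in model.atoms.values():
            serial += 1
            group = "ATOM" if site.is_polymer else "HETATM"
            lines.append(
                f"{group} {serial} {_element_of(site.atom_name)} {site.atom_name} "
                f"{site.residue_type} {site.chain_id} {site.seq_id} "
                f"{site.x:.3f} {site.y:.3f} {site.z:.3f} 1.00 0.00 "
                f"{site.seq_id} {site.residue_type} {site.chain_id} {site.atom_name} "
                f"{model.number}"
            )
    lines.append("#")
    path.write_text("\n".join(lines) + "\n")
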