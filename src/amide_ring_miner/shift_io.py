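"""Read/write assigned chemical shifts and distance restraints (NMR-STAR dialect).

The supported dialect is a single assigned-chemical-shift loop
(``_Atom_chem_shift`` tags) and a single distance-restraint loop
(``_Gen_dist_constraint`` tags) per file; loops may be bare or wrapped in
save frames.  Multi-loop files take the first matching loop with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

from amide_ring_miner import _star

logger = logging.getLogger(__name__)

#: Alternative amide-proton spellings folded onto the canonical name "H".
_AMIDE_ALIASES = {"HN": "H"}


class ShiftFormatError(ValueError):
    """Raised when a file lacks the expected loop structure."""


def canonical_atom_name(name: str) -> str:
    """Canonicalize an atom name ("HN" -> "H"); other names pass through."""
    name = name.strip()
    return _AMIDE_ALIASES.get(name.upper(), name)


@dataclass(frozen=True)
class ChemicalShiftRecord:
    """One assigned chemical shift."""

    entry_id: str
    chain_id: str
    seq_id: int
    residue_type: str
    atom_name: str
    value: float
    ambiguity_code: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite shift value for {self.atom_name}")
        if self.seq_id < 1:
            raise ValueError(f"seq_id must be >= 1, got {self.seq_id}")
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")

    @property
    def atom_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.atom_name)


@dataclass(frozen=True)
class RestraintMember:
    chain_id: str
    seq_id: int
    residue_type: str
    atom_name: str

    @property
    def atom_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.atom_name)


@dataclass(frozen=True)
class DistanceRestraint:
    """A restrained proton pair with full identifiers for both members."""

    entry_id: str
    restraint_id: str
    member_1: RestraintMember
    member_2: RestraintMember
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.member_1 == self.member_2:
            raise ValueError(f"restraint {self.restraint_id}: members are the same atom")
        if self.upper_bound is not None and self.upper_bound <= 0:
            raise ValueError(f"restraint {self.restraint_id}: upper_bound must be > 0")


# ---------------------------------------------------------------------------
# reading

_SHIFT_CATEGORIES = ("atom_chem_shift",)
_RESTRAINT_CATEGORIES = ("gen_dist_constraint",)


def _find_loop(path: Path, categories: tuple[str, ...], kind: str) -> _star.StarLoop:
    loops = [lp for lp in _star.parse_loops(path) if lp.category() in categories]
    if not loops:
        raise ShiftFormatError(f"no {kind} loop found in {path}")
    if len(loops) > 1:
        logger.warning("%s: %d %s loops, taking the first", path, len(loops), kind)
    return loops[0]


def read_shift_records(path: str | Path) -> list[ChemicalShiftRecord]:
    """Parse one assigned-chemical-shift loop into records.

    Rows with missing ('.' or '?') or non-numeric shift values are
    skipped; the skip count is logged and available via
    :func:`read_shift_records_with_report`.
    """
    records, _ = read_shift_records_with_report(path)
    return records


def read_shift_records_with_report(
    path: str | Path,
) -> tuple[list[ChemicalShiftRecord], int]:
    path = Path(path)
    loop = _find_loop(path, _SHIFT_CATEGORIES, "assigned-chemical-shift")
    entry_id = _star.data_block_name(path) or path.stem
    i_chain = loop.tag_index("entity_assembly_id", "auth_asym_id", "chain_id")
    i_seq = loop.tag_index("comp_index_id", "seq_id")
    i_res = loop.tag_index("comp_id", "residue_type")
    i_atom = loop.tag_index("atom_id", "atom_name")
    i_val = loop.tag_index("val", "value")
    i_amb = loop.tag_index("ambiguity_code")
    if None in (i_seq, i_res, i_atom, i_val):
        raise ShiftFormatError(f"shift loop in {path} lacks required tags")
    records: list[ChemicalShiftRecord] = []
    skipped = 0
    for row in loop.rows:
        try:
            value = float(row[i_val])
            if not math.isfinite(value):
                raise ValueError
            amb = None
            if i_amb is not None and row[i_amb] not in (".", "?", ""):
                amb = int(row[i_amb])
            records.append(
                ChemicalShiftRecord(
                    entry_id=entry_id,
                    chain_id=row[i_chain] if i_chain is not None else "A",
                    seq_id=int(row[i_seq]),
                    residue_type=row[i_res].upper(),
                    atom_name=canonical_atom_name(row[i_atom]),
                    value=value,
                    ambiguity_code=amb,
                )
            )
        except (ValueError, IndexError):
            skipped += 1
    if skipped:
        logger.info("%s: skipped %d unparseable shift rows", path, skipped)
    return records, skipped


def read_restraints(path: str | Path) -> list[DistanceRestraint]:
    """Parse one distance-restraint loop; both members fully identified."""
    path = Path(path)
    loop = _find_loop(path, _RESTRAINT_CATEGORIES, "distance-restraint")
    entry_id = _star.data_block_name(path) or path.stem

    def member_indices(suffix: str) -> tuple[int | None, ...]:
        return (
            loop.tag_index(f"entity_assembly_id_{suffix}", f"auth_asym_id_{suffix}"),
            loop.tag_index(f"comp_index_id_{suffix}", f"seq_id_{suffix}"),
            loop.tag_index(f"comp_id_{suffix}"),
            loop.tag_index(f"atom_id_{suffix}"),
        )

    i_id = loop.tag_index("id")
    idx1 = member_indices("1")
    idx2 = member_indices("2")
    i_ub = loop.tag_index("distance_upper_bound_val", "upper_bound")
    if any(i is None for i in idx1[1:]) or any(i is None for i in idx2[1:]):
        raise ShiftFormatError(f"restraint loop in {path} lacks member tags")

    restraints: list[DistanceRestraint] = []
    seen_ids: set[str] = set()
    for irow, row in enumerate(loop.rows):
        members = []
        ok = True
        for i_ch, i_sq, i_rs, i_at in (idx1, idx2):
            atom = row[i_at].strip()
            if atom in (".", "?", ""):
                logger.warning("%s: restraint row %d member missing atom name, rejected", path, irow)
                ok = False
                break
            members.append(
                RestraintMember(
                    chain_id=row[i_ch] if i_ch is not None else "A",
                    seq_id=int(row[i_sq]),
                    residue_type=row[i_rs].upper(),
                    atom_name=canonical_atom_name(atom),
                )
            )
        if not ok:
            continue
        rid = row[i_id] if i_id is not None else str(irow + 1)
        if rid in seen_ids:
            logger.warning("%s: duplicate restraint_id %s, keeping both", path, rid)
        seen_ids.add(rid)
        ub = None
        if i_ub is not None and row[i_ub] not in (".", "?", ""):
            ub = float(row[i_ub])
        restraints.append(
            DistanceRestraint(
                entry_id=entry_id,
                restraint_id=rid,
                member_1=members[0],
                member_2=members[1],
                upper_bound=ub,
            )
        )
    return restraints


# ---------------------------------------------------------------------------
# writing

_SHIFT_TAGS = [
    "_Atom_chem_shift.ID",
    "_Atom_chem_shift.Entity_assembly_ID",
    "_Atom_chem_shift.Comp_index_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Val",
    "_Atom_chem_shift.Ambiguity_code",
]

_RESTRAINT_TAGS = [
    "_Gen_dist_constraint.ID",
    "_Gen_dist_constraint.Entity_assembly_ID_1",
    "_Gen_dist_constraint.Comp_index_ID_1",
    "_Gen_dist_constraint.Comp_ID_1",
    "_Gen_dist_constraint.Atom_ID_1",
    "_Gen_dist_constraint.Entity_assembly_ID_2",
    "_Gen_dist_constraint.Comp_index_ID_2",
    "_Gen_dist_constraint.Comp_ID_2",
    "_Gen_dist_constraint.Atom_ID_2",
    "_Gen_dist_constraint.Distance_upper_bound_val",
]


def _write_loop(path: Path, block_name: str, frame: str, tags: list[str], rows: list[list[str]]) -> None:
    lines = [f"data_{block_name}", "", f"save_{frame}", "   loop_"]
    lines += [f"      {t}" for t in tags]
    lines.append("")
    for row in rows:
        lines.append("      " + " ".join(_star.quote_value(v) for v in row))
    lines += ["   stop_", "save_", ""]
    path.write_text("\n".join(lines))


def write_shift_records(records: list[ChemicalShiftRecord], path: str | Path) -> None:
    """Write records as one assigned-chemical-shift loop (values to 3 dp)."""
    path = Path(path)
    rows = [
        [
            str(i + 1),
            r.chain_id,
            str(r.seq_id),
            r.residue_type,
            r.atom_name,
            f"{r.value:.3f}",
            str(r.ambiguity_code) if r.ambiguity_code is not None else ".",
        ]
        for i, r in enumerate(records)
    ]
    block = records[0].entry_id if records else path.stem
    _write_loop(path, block, "assigned_chemical_shifts", _SHIFT_TAGS, rows)


def write_restraints(restraints: list[DistanceRestraint], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for r in restraints:
        rows.append(
            [
                r.restraint_id,
                r.member_1.chain_id,
                str(r.member_1.seq_id),
                r.member_1.residue_type,
                r.member_1.atom_name,
                r.member_2.chain_id,
                str(r.member_2.seq_id),
                r.member_2.residue_type,
                r.member_2.atom_name,
                f"{r.upper_bound:.3f}" if r.upper_bound is not None else ".",
            ]
        )
    block = restraints[0].entry_id if restraints else path.stem
    _write_loop(path, block, "general_distance_constraints", _RESTRAINT_TAGS, rows)
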