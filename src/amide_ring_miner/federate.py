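"""Federation of shift, structure and restraint data by atom identifiers.

Entries are matched through a shift-entry/structure-entry pair list;
within an entry, records merge on (chain id, sequence id, residue,
atom).  Restraints attach to amides by the (chain, seq) of their amide
member; the aromatic member's geometry is not required to coincide with
the nearest ring.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from amide_ring_miner import ring_geometry, shift_stats
from amide_ring_miner.ring_geometry import AROMATIC_TYPES
from amide_ring_miner.shift_io import ChemicalShiftRecord, DistanceRestraint
from amide_ring_miner.shift_stats import StatsTable, UndefinedZError
from amide_ring_miner.structure_io import Ensemble

logger = logging.getLogger(__name__)


class MappingFormatError(ValueError):
    """Raised for malformed entry-pair mapping files."""


@dataclass(frozen=True)
class EntryPair:
    shift_entry_id: str
    structure_entry_id: str

    def __post_init__(self) -> None:
        if not self.shift_entry_id or not self.structure_entry_id:
            raise ValueError("entry ids must be nonempty")


@dataclass
class MergedAmide:
    """The federated per-amide record."""

    pair: EntryPair
    chain_id: str
    seq_id: int
    residue_type: str
    value: float
    z: float
    z_bin: int
    ring_type: str | None = None
    ring_key: tuple[str, int, str] | None = None
    avg_distance: float | None = None
    avg_azimuth: float | None = None
    restrained: bool = False
    n_restraints: int = 0

    def __post_init__(self) -> None:
        if self.restrained != (self.n_restraints >= 1):
            raise ValueError("restrained iff n_restraints >= 1")
        if (self.avg_distance is None) != (self.ring_key is None):
            raise ValueError("distance present iff ring present")


@dataclass
class MergeResult:
    merged: list[MergedAmide] = field(default_factory=list)
    n_shift_only: int = 0
    n_coord_only: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)
    n_restraints: int = 0
    n_amide_aromatic_restraints: int = 0

    @property
    def n_candidates(self) -> int:
        return len(self.merged) + self.n_shift_only + self.n_coord_only + self.n_skipped


def load_entry_pairs(path: str | Path) -> list[EntryPair]:
    """Parse a JSON array of {shift_id, structure_id} objects.

    Duplicate pairs collapse with a warning; pairs with empty ids are
    rejected with a logged reason.  An empty list is valid.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise MappingFormatError(f"cannot parse mapping file {path}: {exc}") from exc
    if not isinstance(raw, list):
        raise MappingFormatError(f"mapping file {path} must contain a JSON array")
    pairs: list[EntryPair] = []
    seen: set[tuple[str, str]] = set()
    for item in raw:
        if not isinstance(item, dict):
            logger.warning("%s: non-object mapping item rejected: %r", path, item)
            continue
        sid = str(item.get("shift_id") or "")
        xid = str(item.get("structure_id") or "")
        if not sid or not xid:
            logger.warning("%s: pair with empty id rejected: %r", path, item)
            continue
        key = (sid, xid)
        if key in seen:
            logger.warning("%s: duplicate pair %s collapsed", path, key)
            continue
        seen.add(key)
        pairs.append(EntryPair(shift_entry_id=sid, structure_entry_id=xid))
    if not pairs:
        logger.warning("%s: no valid entry pairs", path)
    return pairs


def classify_restraint(
    restraint: DistanceRestraint,
    include_nitrogen_bound: bool = True,
) -> bool:
    """True iff one member is the backbone amide proton (canonical name
    "H") and the other is an aromatic ring proton of PHE/TYR/TRP/HIS;
    order-insensitive."""
    for a, b in ((restraint.member_1, restraint.member_2),
                 (restraint.member_2, restraint.member_1)):
        if a.atom_name != "H":
            continue
        if b.residue_type.upper() not in AROMATIC_TYPES:
            continue
        names = ring_geometry.ring_proton_names(
            b.residue_type, carbon_bound_only=not include_nitrogen_bound
        )
        if b.atom_name in names:
            return True
    return False


def merge_entry(
    pair: EntryPair,
    shifts: list[ChemicalShiftRecord],
    ensemble: Ensemble,
    restraints: list[DistanceRestraint],
    stats: StatsTable,
    include_nitrogen_bound: bool = True,
) -> MergeResult:
    """Merge one entry into per-amide records keyed by atom identifiers.

    A record is emitted per amide 1H with a reported shift AND a
    coordinate in at least one model; amides present on only one side
    are counted, not merged.  Amides whose residue type lacks a usable
    reference statistic are skipped with a reason.
    """
    result = MergeResult(n_restraints=len(restraints))
    classified = [r for r in restraints if classify_restraint(r, include_nitrogen_bound)]
    result.n_amide_aromatic_restraints = len(classified)
    restraint_count: Counter = Counter()
    for r in classified:
        member = r.member_1 if r.member_1.atom_name == "H" else r.member_2
        restraint_count[(member.chain_id, member.seq_id)] += 1

    shift_by_key = {}
    for rec in shifts:
        if rec.atom_name == "H":
            shift_by_key[(rec.chain_id, rec.seq_id)] = rec

    coord_keys = {
        (k[0], k[1]) for m in ensemble.models for k in m.atoms if k[2] == "H"
    }
    result.n_shift_only = len(set(shift_by_key) - coord_keys)
    result.n_coord_only = len(coord_keys - set(shift_by_key))

    rings = ring_geometry.build_ring_instances(ensemble)
    for key in sorted(set(shift_by_key) & coord_keys):
        rec = shift_by_key[key]
        stat = stats.get((rec.residue_type, "H"))
        if stat is None:
            result.n_skipped += 1
            result.skip_reasons[f"no_stats:{rec.residue_type}"] += 1
            continue
        try:
            z = shift_stats.z_score(rec.value, stat)
        except UndefinedZError:
            result.n_skipped += 1
            result.skip_reasons[f"zero_sd:{rec.residue_type}"] += 1
            continue
        assignment = ring_geometry.nearest_ring((key[0], key[1], "H"), ensemble, rings)
        n_restr = restraint_count.get(key, 0)
        result.merged.append(MergedAmide(
            pair=pair,
            chain_id=key[0],
            seq_id=key[1],
            residue_type=rec.residue_type,
            value=rec.value,
            z=z,
            z_bin=shift_stats.z_bin(z),
            ring_type=assignment.ring.residue_type if assignment else None,
            ring_key=assignment.ring.key if assignment else None,
            avg_distance=assignment.avg_distance if assignment else None,
            avg_azimuth=assignment.avg_azimuth if assignment else None,
            restrained=n_restr >= 1,
            n_restraints=n_restr,
        ))
    return result
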