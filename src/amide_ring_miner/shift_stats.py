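"""Filtered reference chemical-shift statistics and Z-scores.

The filtered corpus drops whole entries that carry an aromatic or
paramagnetic ligand flag or any carbon-bound proton shift above 10 ppm
or below -2.5 ppm, and drops individual shifts lying strictly outside
eight standard deviations from the full-corpus mean for their
(residue, atom) type.  Statistics use the population (n) standard
deviation by default.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from amide_ring_miner.shift_io import ChemicalShiftRecord

logger = logging.getLogger(__name__)

CARBON_BOUND_MAX_PPM = 10.0
CARBON_BOUND_MIN_PPM = -2.5
EIGHT_SD = 8.0

StatsMode = Literal["full", "filtered"]
SDDenominator = Literal["population", "sample"]

# ---------------------------------------------------------------------------
# proton topology: bound heavy-atom element per (residue, proton name)
#
# Protons default to carbon-bound; the table lists the exceptions
# (nitrogen-, oxygen- and sulfur-bound protons) per standard residue.

_NON_CARBON_PROTONS: dict[str, dict[str, str]] = {
    "ARG": {"HE": "N", "HH11": "N", "HH12": "N", "HH21": "N", "HH22": "N"},
    "ASN": {"HD21": "N", "HD22": "N"},
    "CYS": {"HG": "S"},
    "GLN": {"HE21": "N", "HE22": "N"},
    "HIS": {"HD1": "N", "HE2": "N"},
    "LYS": {"HZ": "N", "HZ1": "N", "HZ2": "N", "HZ3": "N"},
    "SER": {"HG": "O"},
    "THR": {"HG1": "O"},
    "TRP": {"HE1": "N"},
    "TYR": {"HH": "O"},
}

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def bound_element(residue_type: str, atom_name: str) -> str | None:
    """Heavy-atom element a proton is bonded to, or None for non-protons.

    Unknown residue/atom combinations are treated as carbon-bound only
    for known residues; unknown residues return None with a warning.
    """
    if not atom_name.startswith("H"):
        return None
    residue_type = residue_type.upper()
    if atom_name == "H":  # backbone amide
        return "N"
    if residue_type not in _STANDARD_RESIDUES:
        logger.warning("unknown residue type %s: %s treated as non-carbon-bound",
                       residue_type, atom_name)
        return None
    return _NON_CARBON_PROTONS.get(residue_type, {}).get(atom_name, "C")


def is_carbon_bound_proton(residue_type: str, atom_name: str) -> bool:
    return bound_element(residue_type, atom_name) == "C"


# ---------------------------------------------------------------------------
# types

@dataclass
class ReferenceStatistic:
    """Per-(residue type, atom name) reference distribution."""

    residue_type: str
    atom_name: str
    mean: float
    sd: float
    count: int
    #: bin index (floor(value / bin width)) -> count; None for external tables
    histogram: Counter | None = None
    hist_bin_ppm: float = 0.1
    sd_flagged: bool = False  # count == 1, sd recorded as 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.histogram is not None and sum(self.histogram.values()) != self.count:
            raise ValueError("histogram total must equal count")

    @property
    def key(self) -> tuple[str, str]:
        return (self.residue_type, self.atom_name)


StatsTable = dict[tuple[str, str], ReferenceStatistic]


@dataclass
class FilterReport:
    """Outcome of the entry-level and shift-level filtering rules."""

    entry_id: str
    excluded: bool
    reasons: list[str] = field(default_factory=list)
    #: indices into the record list dropped by the eight-SD rule
    dropped_shifts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded iff reasons nonempty")


class UndefinedZError(ValueError):
    """Z requested against a zero-SD reference statistic."""


# ---------------------------------------------------------------------------
# operations

def entry_filter(
    records: list[ChemicalShiftRecord],
    full_stats: StatsTable | None = None,
    ligand_flags: Mapping[str, bool] | None = None,
    entry_id: str | None = None,
) -> FilterReport:
    """Apply the filtered-data-set rules to one entry.

    Entry-level: aromatic/paramagnetic ligand flags and the carbon-bound
    proton range (> 10 ppm or < -2.5 ppm) exclude the whole entry.
    Shift-level: shifts strictly outside eight SDs from the full-corpus
    mean are listed in ``dropped_shifts`` (exactly 8.000 SD is retained).
    """
    entry_id = entry_id or (records[0].entry_id if records else "")
    flags = ligand_flags or {}
    reasons: list[str] = []
    if flags.get("aromatic_ligand"):
        reasons.append("aromatic_ligand")
    if flags.get("paramagnetic_ligand"):
        reasons.append("paramagnetic_ligand")
    if any(
        is_carbon_bound_proton(r.residue_type, r.atom_name)
        and (r.value > CARBON_BOUND_MAX_PPM or r.value < CARBON_BOUND_MIN_PPM)
        for r in records
    ):
        reasons.append("extreme_carbon_bound_proton")
    dropped: list[int] = []
    if full_stats:
        for i, r in enumerate(records):
            stat = full_stats.get((r.residue_type, r.atom_name))
            if stat is None or stat.sd == 0:
                continue
            # strict "outside eight SD"; 1e-9 guard keeps exactly-8.000 inside
            if abs(r.value - stat.mean) / stat.sd > EIGHT_SD + 1e-9:
                dropped.append(i)
    return FilterReport(
        entry_id=entry_id,
        excluded=bool(reasons),
        reasons=reasons,
        dropped_shifts=dropped,
    )


def _build_table(
    values: Mapping[tuple[str, str], list[float]],
    sd_denominator: SDDenominator,
    hist_bin_ppm: float,
) -> StatsTable:
    table: StatsTable = {}
    for (rtype, atom), vals in sorted(values.items()):
        n = len(vals)
        if n == 0:
            continue
        mean = sum(vals) / n
        if n == 1:
            sd, flagged = 0.0, True
        else:
            denom = n if sd_denominator == "population" else n - 1
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / denom)
            flagged = False
        hist = Counter(math.floor(v / hist_bin_ppm) for v in vals)
        table[(rtype, atom)] = ReferenceStatistic(
            residue_type=rtype,
            atom_name=atom,
            mean=mean,
            sd=sd,
            count=n,
            histogram=hist,
            hist_bin_ppm=hist_bin_ppm,
            sd_flagged=flagged,
        )
    return table


def compute_reference_stats(
    corpus: Mapping[str, list[ChemicalShiftRecord]],
    mode: StatsMode = "full",
    ligand_flags: Mapping[str, Mapping[str, bool]] | None = None,
    sd_denominator: SDDenominator = "population",
    hist_bin_ppm: float = 0.1,
) -> StatsTable:
    """Per-(residue, atom) mean/SD/count/histogram over a corpus.

    ``filtered`` mode applies :func:`entry_filter` per entry first; the
    eight-SD rule is evaluated against the full-mode statistics.
    """
    full_values: dict[tuple[str, str], list[float]] = defaultdict(list)
    for records in corpus.values():
        for r in records:
            full_values[(r.residue_type, r.atom_name)].append(r.value)
    if mode == "full":
        return _build_table(full_values, sd_denominator, hist_bin_ppm)

    full_stats = _build_table(full_values, sd_denominator, hist_bin_ppm)
    flags = ligand_flags or {}
    filtered_values: dict[tuple[str, str], list[float]] = defaultdict(list)
    n_excluded = 0
    for entry_id, records in corpus.items():
        report = entry_filter(records, full_stats, flags.get(entry_id), entry_id)
        if report.excluded:
            n_excluded += 1
            continue
        dropped = set(report.dropped_shifts)
        for i, r in enumerate(records):
            if i in dropped:
                continue
            filtered_values[(r.residue_type, r.atom_name)].append(r.value)
    if n_excluded:
        logger.info("filtered stats: excluded %d of %d entries", n_excluded, len(corpus))
    return _build_table(filtered_values, sd_denominator, hist_bin_ppm)


def z_score(value: float, stat: ReferenceStatistic) -> float:
    """(value - mean) / sd; upfield (smaller ppm) gives negative Z."""
    if stat.sd == 0:
        raise UndefinedZError(
            f"zero reference SD for {stat.residue_type} {stat.atom_name}"
        )
    return (value - stat.mean) / stat.sd


def z_bin(z: float) -> int:
    """Round half away from zero, clamped to [-8, 8]."""
    b = math.floor(abs(z) + 0.5)
    b = int(math.copysign(b, z))
    return max(-8, min(8, b))


# ---------------------------------------------------------------------------
# persistence

def write_stats_table(table: StatsTable, path: str | Path, hist_path: str | Path | None = None) -> None:
    """Persist a table as TSV (plus an optional histogram sidecar)."""
    rows = [
        {
            "residue_type": s.residue_type,
            "atom_name": s.atom_name,
            "count": s.count,
            "mean": s.mean,
            "sd": s.sd,
        }
        for s in table.values()
    ]
    pd.DataFrame(rows, columns=["residue_type", "atom_name", "count", "mean", "sd"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    if hist_path is not None:
        hrows = []
        for s in table.values():
            if s.histogram is None:
                continue
            for b, c in sorted(s.histogram.items()):
                hrows.append(
                    {
                        "residue_type": s.residue_type,
                        "atom_name": s.atom_name,
                        "bin_low_ppm": b * s.hist_bin_ppm,
                        "count": c,
                    }
                )
        pd.DataFrame(
            hrows, columns=["residue_type", "atom_name", "bin_low_ppm", "count"]
        ).to_csv(hist_path, sep="\t", index=False, float_format="%.6f")


def read_stats_table(path: str | Path) -> StatsTable:
    df = pd.read_csv(path, sep="\t")
    table: StatsTable = {}
    for row in df.to_dict("records"):
        stat = ReferenceStatistic(
            residue_type=str(row["residue_type"]),
            atom_name=str(row["atom_name"]),
            mean=float(row["mean"]),
            sd=float(row["sd"]),
            count=int(row["count"]),
            histogram=None,
        )
        table[stat.key] = stat
    return table
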