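"""Z-bin restrained-fraction summaries and the end-to-end pipeline.

``bin_fractions`` conditions denominators on entry-level eligibility
(only amides from entries possessing at least one amide-aromatic
restraint) and reports per-bin counts by default; a switch provides the
global-denominator reading.  Boundary conventions are strict: records
at exactly the distance cutoff are excluded, half-integer Z values bin
away from zero.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from amide_ring_miner import federate, shift_io, shift_stats, structure_io
from amide_ring_miner.federate import EntryPair, MergedAmide
from amide_ring_miner.ring_geometry import AROMATIC_TYPES

logger = logging.getLogger(__name__)

EXTREME_Z = 2.0


@dataclass
class ZBinSummary:
    z_bin: int
    n_total: int
    n_restrained: int
    fraction: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_restrained <= self.n_total:
            raise ValueError("0 <= n_restrained <= n_total required")


@dataclass
class DistanceZRecord:
    aromatic_type: str
    avg_distance: float
    z: float
    restrained: bool
    shift_entry_id: str = ""
    chain_id: str = ""
    seq_id: int = 0


@dataclass
class TypeSummary:
    aromatic_type: str
    n_upfield_extreme: int  # z <= -2
    n_mid: int              # -2 < z < 2
    n_downfield_extreme: int  # z >= 2
    median_extreme_z: float | None


def eligible_entries(merged: list[MergedAmide]) -> set[str]:
    """Shift-entry ids possessing at least one restrained amide."""
    return {m.pair.shift_entry_id for m in merged if m.restrained}


def bin_fractions(
    merged: list[MergedAmide],
    denominator: Literal["per_bin", "global"] = "per_bin",
    eligible: set[str] | None = None,
) -> list[ZBinSummary]:
    """Fraction of restrained amides per Z-score bin.

    Only amides from eligible entries (>= 1 amide-aromatic restraint)
    enter the denominators.
    """
    if eligible is None:
        eligible = eligible_entries(merged)
    pool = [m for m in merged if m.pair.shift_entry_id in eligible]
    if not pool:
        logger.warning("bin_fractions: empty eligible set")
        return []
    n_eligible = len(pool)
    out = []
    for b in sorted({m.z_bin for m in pool}):
        in_bin = [m for m in pool if m.z_bin == b]
        n_restr = sum(1 for m in in_bin if m.restrained)
        denom = n_eligible if denominator == "global" else len(in_bin)
        out.append(ZBinSummary(
            z_bin=b,
            n_total=len(in_bin),
            n_restrained=n_restr,
            fraction=n_restr / denom if denom else None,
        ))
    return out


def distance_z_table(merged: list[MergedAmide], cutoff: float = 8.0) -> list[DistanceZRecord]:
    """One record per amide whose nearest ring is aromatic (HIS/TRP/PHE/
    TYR) with ensemble-averaged distance strictly below the cutoff."""
    out = []
    for m in merged:
        if m.ring_type not in AROMATIC_TYPES:
            continue
        if m.avg_distance is None or not m.avg_distance < cutoff:
            continue
        out.append(DistanceZRecord(
            aromatic_type=m.ring_type,
            avg_distance=m.avg_distance,
            z=m.z,
            restrained=m.restrained,
            shift_entry_id=m.pair.shift_entry_id,
            chain_id=m.chain_id,
            seq_id=m.seq_id,
        ))
    return out


def type_direction_summary(records: list[DistanceZRecord]) -> list[TypeSummary]:
    """Per aromatic type: extreme-upfield/mid/extreme-downfield counts
    and the median Z among |z| >= 2 records."""
    out = []
    for rtype in AROMATIC_TYPES:
        rs = [r for r in records if r.aromatic_type == rtype]
        extreme = [r.z for r in rs if abs(r.z) >= EXTREME_Z]
        out.append(TypeSummary(
            aromatic_type=rtype,
            n_upfield_extreme=sum(1 for r in rs if r.z <= -EXTREME_Z),
            n_mid=sum(1 for r in rs if -EXTREME_Z < r.z < EXTREME_Z),
            n_downfield_extreme=sum(1 for r in rs if r.z >= EXTREME_Z),
            median_extreme_z=statistics.median(extreme) if extreme else None,
        ))
    return out


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    corpus: Path
    out: Path
    mapping: Path | None = None  # default <corpus>/mapping.json
    stats_mode: Literal["full", "filtered"] = "filtered"
    stats_table: Path | None = None  # external reference stats TSV
    cutoff: float = 8.0
    denominator: Literal["per_bin", "global"] = "per_bin"
    include_nitrogen_bound: bool = True
    sd_denominator: Literal["population", "sample"] = "population"
    hist_bin_ppm: float = 0.1

    def __post_init__(self) -> None:
        self.corpus = Path(self.corpus)
        self.out = Path(self.out)
        if self.mapping is None:
            self.mapping = self.corpus / "mapping.json"
        self.mapping = Path(self.mapping)
        if not self.corpus.is_dir():
            raise FileNotFoundError(f"corpus directory not found: {self.corpus}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


def _fmt(v, nd: int = 6) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.{nd}f}"
    return str(v)


def _merged_frame(merged: list[MergedAmide]) -> pd.DataFrame:
    rows = [
        {
            "shift_entry_id": m.pair.shift_entry_id,
            "structure_entry_id": m.pair.structure_entry_id,
            "chain_id": m.chain_id,
            "seq_id": m.seq_id,
            "residue_type": m.residue_type,
            "shift_ppm": _fmt(m.value, 3),
            "z": _fmt(m.z),
            "z_bin": m.z_bin,
            "ring_chain": m.ring_key[0] if m.ring_key else "",
            "ring_seq_id": m.ring_key[1] if m.ring_key else "",
            "ring_id": m.ring_key[2] if m.ring_key else "",
            "ring_type": m.ring_type or "",
            "avg_distance": _fmt(m.avg_distance),
            "avg_azimuth": _fmt(m.avg_azimuth),
            "restrained": int(m.restrained),
            "n_restraints": m.n_restraints,
        }
        for m in merged
    ]
    columns = [
        "shift_entry_id", "structure_entry_id", "chain_id", "seq_id",
        "residue_type", "shift_ppm", "z", "z_bin", "ring_chain", "ring_seq_id",
        "ring_id", "ring_type", "avg_distance", "avg_azimuth", "restrained",
        "n_restraints",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: PipelineConfig) -> Path:
    """Load pairs, read/merge each entry, summarise, and write TSVs.

    Per-entry failures are reported in ``run_report.tsv`` rather than
    aborting the corpus run.  Output is deterministic given the inputs.
    """
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("amide_ring_miner")
    root_logger.addHandler(handler)
    try:
        return _run_pipeline(config, out)
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _run_pipeline(config: PipelineConfig, out: Path) -> Path:
    pairs = federate.load_entry_pairs(config.mapping)
    logger.info("loaded %d entry pairs from %s", len(pairs), config.mapping)

    corpus_shifts: dict[str, list] = {}
    report_rows = []
    for pair in pairs:
        path = config.corpus / "shifts" / f"{pair.shift_entry_id}.str"
        try:
            corpus_shifts[pair.shift_entry_id] = shift_io.read_shift_records(path)
        except (OSError, ValueError) as exc:
            logger.warning("%s: unreadable shifts (%s)", pair.shift_entry_id, exc)

    if config.stats_table is not None:
        stats = shift_stats.read_stats_table(config.stats_table)
        logger.info("loaded external reference stats from %s", config.stats_table)
    else:
        stats = shift_stats.compute_reference_stats(
            corpus_shifts, mode=config.stats_mode,
            sd_denominator=config.sd_denominator,
            hist_bin_ppm=config.hist_bin_ppm,
        )
        shift_stats.write_stats_table(
            stats, out / "reference_stats.tsv", out / "reference_stats_hist.tsv"
        )

    merged: list[MergedAmide] = []
    for pair in pairs:
        row = {
            "shift_entry_id": pair.shift_entry_id,
            "structure_entry_id": pair.structure_entry_id,
            "status": "ok", "n_merged": 0, "n_shift_only": 0, "n_coord_only": 0,
            "n_skipped": 0, "n_restraints": 0, "n_amide_aromatic_restraints": 0,
            "message": "",
        }
        try:
            shifts = corpus_shifts.get(pair.shift_entry_id)
            if shifts is None:
                raise FileNotFoundError("shift file missing or unreadable")
            ensemble = structure_io.read_ensemble(
                config.corpus / "structures" / f"{pair.structure_entry_id}.cif"
            )
            rpath = config.corpus / "restraints" / f"{pair.structure_entry_id}.str"
            restraints = shift_io.read_restraints(rpath) if rpath.exists() else []
            result = federate.merge_entry(
                pair, shifts, ensemble, restraints, stats,
                include_nitrogen_bound=config.include_nitrogen_bound,
            )
            merged.extend(result.merged)
            row.update(
                n_merged=len(result.merged),
                n_shift_only=result.n_shift_only,
                n_coord_only=result.n_coord_only,
                n_skipped=result.n_skipped,
                n_restraints=result.n_restraints,
                n_amide_aromatic_restraints=result.n_amide_aromatic_restraints,
            )
        except (OSError, ValueError, KeyError) as exc:
            row["status"] = "failed"
            row["message"] = str(exc)
            logger.warning("entry %s failed: %s", pair.shift_entry_id, exc)
        report_rows.append(row)

    merged.sort(key=lambda m: (m.pair.shift_entry_id, m.chain_id, m.seq_id))
    _merged_frame(merged).to_csv(out / "merged.tsv", sep="\t", index=False)

    summaries = bin_fractions(merged, denominator=config.denominator)
    pd.DataFrame(
        [
            {"z_bin": s.z_bin, "n_total": s.n_total, "n_restrained": s.n_restrained,
             "fraction": _fmt(s.fraction)}
            for s in summaries
        ],
        columns=["z_bin", "n_total", "n_restrained", "fraction"],
    ).to_csv(out / "zbin_fractions.tsv", sep="\t", index=False)

    dz = distance_z_table(merged, cutoff=config.cutoff)
    pd.DataFrame(
        [
            {"aromatic_type": r.aromatic_type, "avg_distance": _fmt(r.avg_distance),
             "z": _fmt(r.z), "restrained": int(r.restrained),
             "shift_entry_id": r.shift_entry_id, "chain_id": r.chain_id,
             "seq_id": r.seq_id}
            for r in dz
        ],
        columns=["aromatic_type", "avg_distance", "z", "restrained",
                 "shift_entry_id", "chain_id", "seq_id"],
    ).to_csv(out / "distance_z.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"aromatic_type": t.aromatic_type,
             "n_upfield_extreme": t.n_upfield_extreme, "n_mid": t.n_mid,
             "n_downfield_extreme": t.n_downfield_extreme,
             "median_extreme_z": _fmt(t.median_extreme_z)}
            for t in type_direction_summary(dz)
        ],
        columns=["aromatic_type", "n_upfield_extreme", "n_mid",
                 "n_downfield_extreme", "median_extreme_z"],
    ).to_csv(out / "type_summary.tsv", sep="\t", index=False)

    pd.DataFrame(
        report_rows,
        columns=["shift_entry_id", "structure_entry_id", "status", "n_merged",
                 "n_shift_only", "n_coord_only", "n_skipped", "n_restraints",
                 "n_amide_aromatic_restraints", "message"],
    ).to_csv(out / "run_report.tsv", sep="\t", index=False)
    logger.info("pipeline complete: %d merged amides over %d entries",
                len(merged), len(pairs))
    return out
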