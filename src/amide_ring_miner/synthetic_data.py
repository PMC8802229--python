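"""Synthetic corpora with planted ring-current effects and known ground truth.

Structures are deliberately not physically realistic polymers: residues
sit on a coarse 1-D lattice with aromatic rings attached at randomized
orientations.  Geometry correctness (planar rings, ~1.39 A bonds,
exact probe placement) is in scope; conformational realism is not.

Planted amide-shift perturbations follow a point-dipole form
``delta = intensity * B * (1 - 3 cos^2 theta) / r^3`` applied from the
nearest ring within the effect radius, so on-axis amides shift upfield
(negative) and in-plane amides downfield (positive).  When
``probe_delta_sigma`` is set, one amide per eligible aromatic residue is
relocated to a distance where the planted perturbation is exactly that
many reference SDs: on the ring axis (shielded) for PHE/TYR/TRP, in the
ring plane (deshielded) for HIS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from amide_ring_miner import ring_geometry, shift_io, shift_stats, structure_io
from amide_ring_miner.ring_geometry import AROMATIC_TYPES, ring_definitions
from amide_ring_miner.shift_io import ChemicalShiftRecord, DistanceRestraint, RestraintMember
from amide_ring_miner.shift_stats import ReferenceStatistic, StatsTable
from amide_ring_miner.structure_io import AtomSite, Ensemble, Model

RING_BOND = 1.39  # A, aromatic C-C
RING_H_BOND = 1.02  # A, radial offset of ring protons past the ring atom
HEX_RADIUS = RING_BOND  # regular hexagon: side == circumradius
PENT_RADIUS = RING_BOND / (2.0 * math.sin(math.pi / 5.0))
PENT_APOTHEM = RING_BOND / (2.0 * math.tan(math.pi / 5.0))

#: default approximate amide 1H reference means (ppm); SD uniform on purpose
#: so a single amplitude plants the same effect in sigma units everywhere.
_DEFAULT_H_MEAN = {
    "ALA": 8.19, "ARG": 8.23, "ASN": 8.32, "ASP": 8.30, "CYS": 8.38,
    "GLN": 8.21, "GLU": 8.33, "GLY": 8.33, "HIS": 8.25, "ILE": 8.26,
    "LEU": 8.22, "LYS": 8.17, "MET": 8.26, "PHE": 8.36, "PRO": 8.20,
    "SER": 8.28, "THR": 8.24, "TRP": 8.28, "TYR": 8.32, "VAL": 8.28,
}
DEFAULT_H_SD = 0.60

_NON_AROMATIC_POOL = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "ILE", "LEU",
    "LYS", "MET", "SER", "THR", "VAL",
)  # PRO excluded so every non-first residue carries an amide proton

_SIX_MEMBERS = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
_PENT_MEMBERS_HIS = ("CG", "ND1", "CE1", "NE2", "CD2")
_TRP_SIX = ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")
_TRP_FIVE = ("CG", "CD1", "NE1", "CE2", "CD2")

_RING_PROTON_PARENT = {
    "PHE": {"HD1": "CD1", "HD2": "CD2", "HE1": "CE1", "HE2": "CE2", "HZ": "CZ"},
    "TYR": {"HD1": "CD1", "HD2": "CD2", "HE1": "CE1", "HE2": "CE2"},
    "HIS": {"HD1": "ND1", "HD2": "CD2", "HE1": "CE1", "HE2": "NE2"},
    "TRP": {"HD1": "CD1", "HE1": "NE1", "HE3": "CE3",
            "HZ2": "CZ2", "HZ3": "CZ3", "HH2": "CH2"},
}


class InvalidConfigError(ValueError):
    pass


def default_ring_intensities() -> dict[tuple[str, str], float]:
    """(residue type, ring id) -> dimensionless ring-current intensity."""
    out = {}
    for rtype, defs in ring_definitions().items():
        for rd in defs:
            out[(rtype, rd.ring_id)] = rd.intensity
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for one synthetic corpus; identical config+seed gives a
    byte-identical corpus."""

    n_entries: int = 3
    chain_length: int = 20
    aromatic_fraction: float = 0.3
    n_models: int = 3
    noise_sd_scale: float = 1.0
    effect_amplitude_B: float = 30.42  # ppm * A^3
    ring_intensity: Mapping[tuple[str, str], float] | None = None
    restraint_cutoff: float = 5.0
    seed: int = 0
    # generator extensions (see module docstring)
    lattice_spacing: float = 15.0
    model_jitter_sd: float = 0.05
    probe_delta_sigma: float | None = None
    decoy_fraction: float = 0.2
    effect_radius: float = 8.0

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise InvalidConfigError("n_entries must be >= 1")
        if self.n_models < 1:
            raise InvalidConfigError("n_models must be >= 1")
        if not 0.0 <= self.aromatic_fraction <= 1.0:
            raise InvalidConfigError("aromatic_fraction must be in [0, 1]")
        if self.restraint_cutoff <= 0:
            raise InvalidConfigError("restraint_cutoff must be > 0")
        if self.chain_length < 2:
            raise InvalidConfigError("chain_length must be >= 2")

    def intensities(self) -> Mapping[tuple[str, str], float]:
        return self.ring_intensity or default_ring_intensities()


@dataclass
class GroundTruthRow:
    shift_entry_id: str
    structure_entry_id: str
    chain_id: str
    seq_id: int
    residue_type: str
    planted_delta: float
    ring_key: tuple[str, int, str] | None  # (chain, seq, ring_id)
    ring_type: str | None
    avg_distance: float | None
    avg_azimuth: float | None
    per_model_distances: list[float] = field(default_factory=list)
    per_model_azimuths: list[float] = field(default_factory=list)


@dataclass
class GroundTruth:
    rows: list[GroundTruthRow] = field(default_factory=list)

    def by_amide(self) -> dict[tuple[str, str, int], GroundTruthRow]:
        return {(r.shift_entry_id, r.chain_id, r.seq_id): r for r in self.rows}


def ring_current_delta(r: float, theta_deg: float, intensity: float, B: float) -> float:
    """Point-dipole perturbation in ppm: i * B * (1 - 3 cos^2 theta) / r^3."""
    if r <= 0:
        raise ValueError(f"distance must be > 0, got {r}")
    c = math.cos(math.radians(theta_deg))
    return intensity * B * (1.0 - 3.0 * c * c) / r**3


def default_reference_stats() -> StatsTable:
    """Generator reference table: per-residue amide 1H mean, uniform SD."""
    table: StatsTable = {}
    for rtype, mean in _DEFAULT_H_MEAN.items():
        table[(rtype, "H")] = ReferenceStatistic(
            residue_type=rtype, atom_name="H", mean=mean, sd=DEFAULT_H_SD,
            count=1000, histogram=None,
        )
    return table


# ---------------------------------------------------------------------------
# structure generation

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _plane_basis(normal: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(normal, ref))
    e2 = np.cross(normal, e1)
    phase = rng.uniform(0, 2 * math.pi)
    return (math.cos(phase) * e1 + math.sin(phase) * e2,
            -math.sin(phase) * e1 + math.cos(phase) * e2)


def _polygon(center: np.ndarray, e1: np.ndarray, e2: np.ndarray,
             radius: float, n: int, phase: float = 0.0) -> list[np.ndarray]:
    return [
        center + radius * (math.cos(phase + 2 * math.pi * k / n) * e1
                           + math.sin(phase + 2 * math.pi * k / n) * e2)
        for k in range(n)
    ]


def _build_ring_atoms(
    rtype: str, cb: np.ndarray, rng: np.random.Generator,
    avoid: list[np.ndarray], min_clearance: float = 2.5,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Ring member and ring-proton coordinates plus per-ring anchors.

    The ring center is resampled (up to 50 tries) so it stays at least
    ``min_clearance`` from the positions in ``avoid`` (existing amide
    protons), keeping planted perturbations bounded.
    """
    for _ in range(50):
        direction = _random_unit(rng)
        center = cb + 2.2 * direction
        if all(np.linalg.norm(center - p) >= min_clearance for p in avoid):
            break
    normal = _random_unit(rng)
    e1, e2 = _plane_basis(normal, rng)
    atoms: dict[str, np.ndarray] = {}
    anchors: dict[str, np.ndarray] = {}

    if rtype in ("PHE", "TYR"):
        verts = _polygon(center, e1, e2, HEX_RADIUS, 6)
        atoms.update(zip(_SIX_MEMBERS, verts))
        anchors["six"] = center
    elif rtype == "HIS":
        verts = _polygon(center, e1, e2, PENT_RADIUS, 5)
        atoms.update(zip(_PENT_MEMBERS_HIS, verts))
        anchors["five"] = center
    elif rtype == "TRP":
        verts = _polygon(center, e1, e2, HEX_RADIUS, 6)
        atoms.update(zip(_TRP_SIX, verts))
        anchors["six"] = center
        # fuse the regular pentagon coplanar on the CD2-CE2 edge
        cd2, ce2 = atoms["CD2"], atoms["CE2"]
        mid = 0.5 * (cd2 + ce2)
        p5c = mid + PENT_APOTHEM * _unit(mid - center)
        anchors["five"] = p5c

        def angle_of(p: np.ndarray) -> float:
            v = p - p5c
            return math.atan2(float(np.dot(v, e2)), float(np.dot(v, e1)))

        step = 2 * math.pi / 5
        a_ce2, a_cd2 = angle_of(ce2), angle_of(cd2)
        # direction around the pentagon that leads from CE2 to CD2
        diff = (a_cd2 - a_ce2 + math.pi) % (2 * math.pi) - math.pi
        s = 1.0 if diff > 0 else -1.0
        for k, name in enumerate(("NE1", "CD1", "CG"), start=1):
            ang = a_ce2 - s * step * k
            atoms[name] = p5c + PENT_RADIUS * (math.cos(ang) * e1 + math.sin(ang) * e2)
    else:
        raise ValueError(f"not an aromatic residue type: {rtype}")

    protons: dict[str, np.ndarray] = {}
    ring_center_of = {m: anchors["six"] for m in _TRP_SIX} if rtype == "TRP" else {}
    if rtype == "TRP":
        for m in _TRP_FIVE:
            ring_center_of.setdefault(m, anchors["five"])
    for hname, parent in _RING_PROTON_PARENT[rtype].items():
        pos = atoms[parent]
        c = ring_center_of.get(parent, next(iter(anchors.values())))
        protons[hname] = pos + RING_H_BOND * _unit(pos - c)
    return {**atoms, **protons}, anchors


def _probe_geometry(
    rtype: str, anchors: dict[str, np.ndarray], normal_dir: np.ndarray,
    e1: np.ndarray, target_delta: float, intensities: Mapping[tuple[str, str], float],
    B: float,
) -> tuple[np.ndarray, str] | None:
    """Position for a probe amide proton planting exactly ``target_delta``
    sigma, and the ring id it references."""
    if rtype == "HIS":
        i = intensities[("HIS", "five")]
        r = (i * B / target_delta) ** (1.0 / 3.0)  # in-plane: factor +1
        # bisect two pentagon vertices to avoid sitting on an atom
        ang = math.pi / 5.0
        direction = math.cos(ang) * e1 + math.sin(ang) * np.cross(normal_dir, e1)
        return anchors["five"] + r * direction, "five"
    ring_id = "six"
    i = intensities[(rtype, ring_id)]
    r = (2.0 * i * B / target_delta) ** (1.0 / 3.0)  # on-axis: factor -2
    return anchors[ring_id] + r * normal_dir, ring_id


def _residue_types(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    types = []
    for _ in range(config.chain_length):
        if rng.random() < config.aromatic_fraction:
            types.append(AROMATIC_TYPES[rng.integers(len(AROMATIC_TYPES))])
        else:
            types.append(_NON_AROMATIC_POOL[rng.integers(len(_NON_AROMATIC_POOL))])
    return types


def generate_structure(config: SyntheticConfig, entry_index: int) -> Ensemble:
    """Build one multi-model ensemble on a coarse lattice.

    Every aromatic residue carries a geometrically planar ring; every
    residue after the first carries a backbone amide proton site; models
    differ by small Gaussian perturbations of non-ring, non-probe atoms.
    Ring anchor points and probe bookkeeping land in ``ensemble.meta``.
    """
    rng = np.random.default_rng([config.seed, entry_index, 0])
    chain = "A"
    types = _residue_types(config, rng)

    base: dict[tuple[str, int, str], tuple[str, np.ndarray]] = {}
    fixed: set[tuple[str, int, str]] = set()  # atoms exempt from model jitter
    ring_atom_names: dict[int, set[str]] = {}
    anchors_meta: dict[tuple[str, int, str], np.ndarray] = {}
    normals_meta: dict[tuple[str, int, str], np.ndarray] = {}
    amide_positions: list[np.ndarray] = []

    for i, rtype in enumerate(types, start=1):
        origin = np.array([i * config.lattice_spacing, 0.0, 0.0])
        origin += rng.uniform(-1.0, 1.0, size=3) * np.array([0.3, 1.0, 1.0])
        n_pos = origin
        ca = n_pos + np.array([1.2, 0.6, 0.3])
        coords = {
            "N": n_pos,
            "CA": ca,
            "HA": ca + np.array([0.3, -0.9, 0.4]),
            "C": ca + np.array([1.3, 0.0, -0.4]),
            "O": ca + np.array([1.7, 1.0, -0.1]),
        }
        if i >= 2:
            coords["H"] = n_pos + np.array([-0.6, 0.8, 0.0])
            amide_positions.append(coords["H"])
        if rtype != "GLY":
            coords["CB"] = ca + np.array([0.2, 1.2, 0.9])
        if rtype in AROMATIC_TYPES:
            ring_coords, anchors = _build_ring_atoms(rtype, coords["CB"], rng, amide_positions)
            coords.update(ring_coords)
            ring_atom_names[i] = set(ring_coords)
            for ring_id, center in anchors.items():
                anchors_meta[(chain, i, ring_id)] = center
                members = {
                    ("PHE", "six"): _SIX_MEMBERS, ("TYR", "six"): _SIX_MEMBERS,
                    ("HIS", "five"): _PENT_MEMBERS_HIS,
                    ("TRP", "six"): _TRP_SIX, ("TRP", "five"): _TRP_FIVE,
                }[(rtype, ring_id)]
                v1 = ring_coords[members[0]] - center
                v2 = ring_coords[members[1]] - center
                normals_meta[(chain, i, ring_id)] = _unit(np.cross(v1, v2))
        for name, pos in coords.items():
            base[(chain, i, name)] = (rtype, pos)

    # probe relocation: exact-perturbation amides on ring axes / planes
    probes: dict[tuple[str, int, str], dict] = {}
    if config.probe_delta_sigma is not None and config.effect_amplitude_B > 0:
        intens = config.intensities()
        target = config.probe_delta_sigma * DEFAULT_H_SD
        for i, rtype in enumerate(types, start=1):
            j = i + 1
            if rtype not in AROMATIC_TYPES or j > config.chain_length:
                continue
            if types[j - 1] in AROMATIC_TYPES:
                continue
            key_anchor = {rid: anchors_meta[(chain, i, rid)]
                          for rid in ("six", "five") if (chain, i, rid) in anchors_meta}
            ring_id0 = "six" if (chain, i, "six") in anchors_meta else "five"
            normal = normals_meta[(chain, i, ring_id0)]
            e1, _ = _plane_basis(normal, np.random.default_rng([config.seed, entry_index, 7, i]))
            pos_rid = _probe_geometry(rtype, key_anchor, normal, e1, target, intens,
                                      config.effect_amplitude_B)
            if pos_rid is None:
                continue
            pos, rid = pos_rid
            hkey = (chain, j, "H")
            base[hkey] = (base[hkey][0], pos)
            fixed.add(hkey)
            probes[hkey] = {
                "ring_key": (chain, i, rid),
                "ring_type": rtype,
                "theta_deg": 90.0 if rtype == "HIS" else 0.0,
            }

    for i in ring_atom_names:
        for name in ring_atom_names[i]:
            fixed.add((chain, i, name))

    models: list[Model] = []
    for m in range(1, config.n_models + 1):
        model = Model(number=m)
        for key, (rtype, pos) in base.items():
            p = pos
            if m > 1 and key not in fixed:
                p = pos + rng.normal(scale=config.model_jitter_sd, size=3)
            model.add(AtomSite(
                chain_id=key[0], seq_id=key[1], residue_type=types[key[1] - 1],
                atom_name=key[2], x=float(p[0]), y=float(p[1]), z=float(p[2]),
            ))
        models.append(model)

    ens = Ensemble(entry_id=f"X{entry_index + 1:04d}", models=models)
    ens.meta["ring_anchors"] = anchors_meta
    ens.meta["ring_normals"] = normals_meta
    ens.meta["probes"] = probes
    ens.meta["residue_types"] = {(chain, i): t for i, t in enumerate(types, start=1)}
    return ens


# ---------------------------------------------------------------------------
# planting

def _ring_geoms_per_model(ensemble: Ensemble) -> dict[tuple[str, int, str], dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Brute-force per-model (center, normal) for every complete ring.

    Intentionally independent of :mod:`amide_ring_miner.ring_geometry`
    so generator and analyzer provide two routes to the same geometry.
    """
    member_sets = {
        ("PHE", "six"): _SIX_MEMBERS, ("TYR", "six"): _SIX_MEMBERS,
        ("HIS", "five"): _PENT_MEMBERS_HIS,
        ("TRP", "six"): _TRP_SIX, ("TRP", "five"): _TRP_FIVE,
    }
    out: dict[tuple[str, int, str], dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for (chain, seq), rtype in ensemble.residue_types().items():
        if rtype not in AROMATIC_TYPES:
            continue
        for (rt, ring_id), members in member_sets.items():
            if rt != rtype:
                continue
            per_model: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for model in ensemble.models:
                try:
                    pts = np.array([model.atoms[(chain, seq, a)].coords for a in members])
                except KeyError:
                    continue
                center = pts.mean(axis=0)
                n = np.cross(pts[0] - center, pts[1] - center)
                per_model[model.number] = (center, n / np.linalg.norm(n))
            if per_model:
                out[(chain, seq, ring_id)] = per_model
    return out


def plant_shifts(
    ensemble: Ensemble,
    stats: StatsTable,
    config: SyntheticConfig,
    seed: int | None = None,
    entry_id: str | None = None,
) -> tuple[list[ChemicalShiftRecord], GroundTruth]:
    """Amide 1H shifts = reference mean + scaled Gaussian noise + planted
    ring-current perturbation from the nearest ring within the effect radius."""
    entry_id = entry_id or ensemble.entry_id
    rng = np.random.default_rng([config.seed if seed is None else seed, 1])
    intens = config.intensities()
    ring_geoms = _ring_geoms_per_model(ensemble)
    ring_types = ensemble.residue_types()

    records: list[ChemicalShiftRecord] = []
    truth = GroundTruth()
    amide_keys = sorted(
        {k for m in ensemble.models for k in m.atoms if k[2] == "H"}
    )
    for key in amide_keys:
        chain, seq, _ = key
        rtype = ring_types[(chain, seq)]
        if (rtype, "H") not in stats:
            raise KeyError(f"no reference statistic for residue type {rtype} (atom H)")
        stat = stats[(rtype, "H")]

        proton = {m.number: m.atoms[key].coords for m in ensemble.models if key in m.atoms}
        best_key = None
        best_d = math.inf
        best_detail: tuple[list[float], list[float]] = ([], [])
        for ring_key, per_model in sorted(ring_geoms.items()):
            shared = sorted(set(proton) & set(per_model))
            if not shared:
                continue
            ds, ths = [], []
            for mnum in shared:
                center, normal = per_model[mnum]
                v = proton[mnum] - center
                d = float(np.linalg.norm(v))
                ds.append(d)
                cosang = abs(float(np.dot(v / d, normal))) if d > 1e-12 else 1.0
                ths.append(math.degrees(math.acos(min(cosang, 1.0))))
            avg_d = sum(ds) / len(ds)
            if avg_d < best_d - 1e-12:
                best_d, best_key, best_detail = avg_d, ring_key, (ds, ths)

        delta = 0.0
        avg_th = None
        if best_key is not None and best_d < config.effect_radius:
            avg_th = sum(best_detail[1]) / len(best_detail[1])
            i = intens[(ring_types[best_key[:2]], best_key[2])]
            delta = ring_current_delta(best_d, avg_th, i, config.effect_amplitude_B)

        noise = float(rng.normal()) * config.noise_sd_scale * stat.sd
        value = stat.mean + noise + delta
        records.append(ChemicalShiftRecord(
            entry_id=entry_id, chain_id=chain, seq_id=seq,
            residue_type=rtype, atom_name="H", value=value,
        ))
        in_radius = best_key is not None and best_d < config.effect_radius
        truth.rows.append(GroundTruthRow(
            shift_entry_id=entry_id,
            structure_entry_id=ensemble.entry_id,
            chain_id=chain, seq_id=seq, residue_type=rtype,
            planted_delta=delta,
            ring_key=best_key if in_radius else None,
            ring_type=ring_types[best_key[:2]] if in_radius else None,
            avg_distance=best_d if best_key is not None else None,
            avg_azimuth=avg_th,
            per_model_distances=best_detail[0],
            per_model_azimuths=best_detail[1],
        ))
    return records, truth


# ---------------------------------------------------------------------------
# restraints

def generate_restraints(
    ensemble: Ensemble,
    cutoff: float,
    seed: int,
    decoy_fraction: float = 0.2,
    entry_id: str | None = None,
) -> list[DistanceRestraint]:
    """One restraint per (amide 1H, aromatic ring 1H) pair whose
    model-averaged distance is <= cutoff, plus random decoy pairs between
    other protons (~``decoy_fraction`` of the emitted total)."""
    entry_id = entry_id or ensemble.entry_id
    rng = np.random.default_rng([seed, 2])
    rtypes = ensemble.residue_types()
    roster = sorted(ensemble.common_roster())

    amides = [k for k in roster if k[2] == "H"]
    ring_h = [
        k for k in roster
        if rtypes[k[:2]] in AROMATIC_TYPES
        and k[2] in ring_geometry.ring_proton_names(rtypes[k[:2]])
    ]
    other_h = [k for k in roster if k[2].startswith("H") and k not in set(amides) | set(ring_h)]

    def avg_dist(a: tuple, b: tuple) -> float:
        ds = [
            np.linalg.norm(m.atoms[a].coords - m.atoms[b].coords)
            for m in ensemble.models
        ]
        return float(np.mean(ds))

    def member(k: tuple) -> RestraintMember:
        return RestraintMember(chain_id=k[0], seq_id=k[1],
                               residue_type=rtypes[k[:2]], atom_name=k[2])

    restraints: list[DistanceRestraint] = []
    rid = 0
    if amides and ring_h:
        am_coords = np.array([[m.atoms[a].coords for a in amides] for m in ensemble.models])
        rh_coords = np.array([[m.atoms[b].coords for b in ring_h] for m in ensemble.models])
        # (models, n_am, n_rh) pairwise distances, averaged over models
        diff = am_coords[:, :, None, :] - rh_coords[:, None, :, :]
        avg = np.linalg.norm(diff, axis=-1).mean(axis=0)
        for ia, a in enumerate(amides):
            for ib, b in enumerate(ring_h):
                if avg[ia, ib] <= cutoff:
                    rid += 1
                    restraints.append(DistanceRestraint(
                        entry_id=entry_id, restraint_id=str(rid),
                        member_1=member(a), member_2=member(b),
                        upper_bound=cutoff,
                    ))

    n_true = len(restraints)
    if other_h and decoy_fraction > 0 and n_true:
        n_decoy = max(1, round(n_true * decoy_fraction / (1.0 - decoy_fraction)))
        for _ in range(n_decoy):
            a = other_h[rng.integers(len(other_h))]
            b = other_h[rng.integers(len(other_h))]
            if a == b:
                continue
            rid += 1
            restraints.append(DistanceRestraint(
                entry_id=entry_id, restraint_id=str(rid),
                member_1=member(a), member_2=member(b),
                upper_bound=round(avg_dist(a, b) + 0.5, 3),
            ))
    return restraints


# ---------------------------------------------------------------------------
# corpus writer

@dataclass
class CorpusPaths:
    root: Path
    shift_files: list[Path]
    restraint_files: list[Path]
    structure_files: list[Path]
    mapping: Path
    ground_truth: Path
    reference_stats: Path


def shift_entry_id(index: int) -> str:
    return f"S{index + 1:04d}"


def structure_entry_id(index: int) -> str:
    return f"X{index + 1:04d}"


def write_fixture_corpus(config: SyntheticConfig, out_dir: str | Path) -> CorpusPaths:
    """Write a complete corpus: NMR-STAR shifts and restraints, mmCIF
    ensembles, the entry-pair mapping, reference stats, and the
    ground-truth sidecar (one row per amide proton)."""
    import pandas as pd

    root = Path(out_dir)
    for sub in ("shifts", "restraints", "structures"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    stats = default_reference_stats()
    shift_files, restraint_files, structure_files = [], [], []
    mapping = []
    gt_rows = []
    for e in range(config.n_entries):
        sid, xid = shift_entry_id(e), structure_entry_id(e)
        ens = generate_structure(config, e)
        ens.entry_id = xid
        records, truth = plant_shifts(
            ens, stats, config, seed=config.seed * 100003 + e, entry_id=sid
        )
        restraints = generate_restraints(
            ens, config.restraint_cutoff, seed=config.seed * 100003 + e,
            decoy_fraction=config.decoy_fraction, entry_id=xid,
        )
        sp = root / "shifts" / f"{sid}.str"
        rp = root / "restraints" / f"{xid}.str"
        xp = root / "structures" / f"{xid}.cif"
        shift_io.write_shift_records(records, sp)
        shift_io.write_restraints(restraints, rp)
        structure_io.write_ensemble(ens, xp)
        shift_files.append(sp)
        restraint_files.append(rp)
        structure_files.append(xp)
        mapping.append({"shift_id": sid, "structure_id": xid})
        for row in truth.rows:
            gt_rows.append({
                "shift_entry_id": row.shift_entry_id,
                "structure_entry_id": row.structure_entry_id,
                "chain_id": row.chain_id,
                "seq_id": row.seq_id,
                "residue_type": row.residue_type,
                "planted_delta_ppm": row.planted_delta,
                "ring_chain": row.ring_key[0] if row.ring_key else "",
                "ring_seq_id": row.ring_key[1] if row.ring_key else "",
                "ring_id": row.ring_key[2] if row.ring_key else "",
                "ring_type": row.ring_type or "",
                "avg_distance": row.avg_distance if row.avg_distance is not None else "",
                "avg_azimuth": row.avg_azimuth if row.avg_azimuth is not None else "",
                "model_distances": ";".join(f"{d:.6f}" for d in row.per_model_distances),
                "model_azimuths": ";".join(f"{t:.6f}" for t in row.per_model_azimuths),
            })

    mapping_path = root / "mapping.json"
    mapping_path.write_text(json.dumps(mapping, indent=1, sort_keys=True) + "\n")
    gt_path = root / "ground_truth.tsv"
    pd.DataFrame(gt_rows).to_csv(gt_path, sep="\t", index=False, float_format="%.9f")
    stats_path = root / "reference_stats.tsv"
    shift_stats.write_stats_table(stats, stats_path)
    (root / "config.json").write_text(
        json.dumps(
            {k: (dict(v) if isinstance(v, Mapping) else v)
             for k, v in vars(replace(config)).items()
             if k != "ring_intensity" or v is None},
            indent=1, sort_keys=True, default=str,
        ) + "\n"
    )
    return CorpusPaths(
        root=root, shift_files=shift_files, restraint_files=restraint_files,
        structure_files=structure_files, mapping=mapping_path,
        ground_truth=gt_path, reference_stats=stats_path,
    )
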