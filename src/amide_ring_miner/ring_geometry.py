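"""Aromatic ring definitions and proton-ring geometry.

Ring centers are centroids of the member atoms; the ring normal is the
cross product of the first two (member - center) vectors in the defined
member order; the azimuth between the normal and the center-to-proton
vector is folded to [0, 90] degrees because the normal's sign is
arbitrary.  Per-model distances and azimuths are averaged over the
ensemble, and the nearest ring is the one minimizing the ensemble-
averaged distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from amide_ring_miner.structure_io import Ensemble


class DegenerateRingError(ValueError):
    """First two member vectors are colinear; no plane normal exists."""


class UndefinedAzimuthError(ValueError):
    """Proton coincides with the ring center."""


@dataclass(frozen=True)
class RingDefinition:
    residue_type: str
    ring_id: str  # "six" | "five"
    member_atom_names: tuple[str, ...]
    ring_proton_names: tuple[str, ...]
    #: ring protons bonded to carbon (subset of ring_proton_names)
    carbon_bound_protons: tuple[str, ...]
    intensity: float = 1.0  # relative ring-current intensity (generator use)

    def __post_init__(self) -> None:
        if len(self.member_atom_names) < 5:
            raise ValueError("ring needs >= 5 members")
        if len(set(self.member_atom_names)) != len(self.member_atom_names):
            raise ValueError("ring member names must be unique")


_RING_DEFS: tuple[RingDefinition, ...] = (
    RingDefinition(
        "PHE", "six",
        ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
        ("HD1", "HD2", "HE1", "HE2", "HZ"),
        ("HD1", "HD2", "HE1", "HE2", "HZ"),
        intensity=1.00,
    ),
    RingDefinition(
        "TYR", "six",
        ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
        ("HD1", "HD2", "HE1", "HE2"),
        ("HD1", "HD2", "HE1", "HE2"),
        intensity=1.00,
    ),
    RingDefinition(
        "HIS", "five",
        ("CG", "ND1", "CE1", "NE2", "CD2"),
        ("HD1", "HD2", "HE1", "HE2"),  # HD1/HE2 are nitrogen-bound
        ("HD2", "HE1"),
        intensity=0.53,
    ),
    RingDefinition(
        "TRP", "six",
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
        ("HE3", "HZ2", "HZ3", "HH2"),
        ("HE3", "HZ2", "HZ3", "HH2"),
        intensity=1.04,
    ),
    RingDefinition(
        "TRP", "five",
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("HD1", "HE1"),  # HE1 is nitrogen-bound
        ("HD1",),
        intensity=0.90,
    ),
)

AROMATIC_TYPES = ("HIS", "PHE", "TRP", "TYR")


def ring_definitions() -> dict[str, tuple[RingDefinition, ...]]:
    """Ring definitions keyed by residue type (TRP carries two rings)."""
    out: dict[str, list[RingDefinition]] = {}
    for rd in _RING_DEFS:
        out.setdefault(rd.residue_type, []).append(rd)
    return {k: tuple(v) for k, v in out.items()}


def ring_proton_names(residue_type: str, carbon_bound_only: bool = False) -> frozenset[str]:
    """All ring-proton names for a residue type, across its rings."""
    names: set[str] = set()
    for rd in ring_definitions().get(residue_type.upper(), ()):
        names.update(rd.carbon_bound_protons if carbon_bound_only else rd.ring_proton_names)
    return frozenset(names)


def export_ring_definitions() -> list[dict]:
    """JSON-serializable reference table of the ring definitions."""
    return [
        {
            "residue_type": rd.residue_type,
            "ring_id": rd.ring_id,
            "members": list(rd.member_atom_names),
            "ring_protons": list(rd.ring_proton_names),
            "carbon_bound_protons": list(rd.carbon_bound_protons),
            "intensity": rd.intensity,
        }
        for rd in _RING_DEFS
    ]


# ---------------------------------------------------------------------------
# elemental geometry

def ring_center(member_coords: np.ndarray) -> np.ndarray:
    """Centroid of the member coordinates, shape (n, 3) -> (3,)."""
    coords = np.asarray(member_coords, dtype=float)
    return coords.mean(axis=0)


def ring_normal(member_coords: np.ndarray) -> np.ndarray:
    """Unit cross product of the first two (member - center) vectors."""
    coords = np.asarray(member_coords, dtype=float)
    center = ring_center(coords)
    v1 = coords[0] - center
    v2 = coords[1] - center
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise DegenerateRingError("first two ring-member vectors are colinear")
    return n / norm


def proton_ring_distance(proton: np.ndarray, center: np.ndarray) -> float:
    """Euclidean distance from proton position to ring center, in Angstrom."""
    return float(np.linalg.norm(np.asarray(proton, float) - np.asarray(center, float)))


def azimuth(proton: np.ndarray, center: np.ndarray, normal: np.ndarray) -> float:
    """Angle (degrees, folded to [0, 90]) between the ring normal and
    the center-to-proton vector."""
    v = np.asarray(proton, float) - np.asarray(center, float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise UndefinedAzimuthError("proton coincides with ring center")
    cosang = abs(float(np.dot(v / norm, np.asarray(normal, float))))
    cosang = min(cosang, 1.0)
    return math.degrees(math.acos(cosang))


# ---------------------------------------------------------------------------
# ring instances over ensembles

@dataclass
class RingInstance:
    chain_id: str
    seq_id: int
    residue_type: str
    ring_id: str
    #: model number -> (center, unit normal)
    per_model: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.ring_id)


@dataclass
class RingAssignment:
    amide_key: tuple[str, int, str]
    ring: RingInstance
    avg_distance: float
    avg_azimuth: float
    per_model_distances: dict[int, float]


def build_ring_instances(ensemble: Ensemble) -> list[RingInstance]:
    """Per-model centers and normals for every complete aromatic ring.

    Rings are taken from any chain; models missing a member atom simply
    do not define the ring in that model.  Non-polymer sites never seed
    rings.
    """
    defs = ring_definitions()
    instances: dict[tuple[str, int, str], RingInstance] = {}
    for (chain, seq), rtype in sorted(ensemble.residue_types().items()):
        for rd in defs.get(rtype, ()):
            inst = RingInstance(chain, seq, rtype, rd.ring_id)
            for model in ensemble.models:
                sites = [model.atoms.get((chain, seq, a)) for a in rd.member_atom_names]
                if any(s is None or not s.is_polymer for s in sites):
                    continue
                coords = np.array([[s.x, s.y, s.z] for s in sites])
                center = ring_center(coords)
                try:
                    normal = ring_normal(coords)
                except DegenerateRingError:
                    continue
                inst.per_model[model.number] = (center, normal)
            if inst.per_model:
                instances[inst.key] = inst
    return [instances[k] for k in sorted(instances)]


def nearest_ring(
    amide_key: tuple[str, int, str],
    ensemble: Ensemble,
    rings: list[RingInstance],
) -> RingAssignment | None:
    """Ring minimizing the ensemble-averaged proton-center distance.

    Averages run over models where both the proton and the full ring are
    defined.  Ties below 1e-6 Angstrom resolve to the lexicographically
    smallest (chain, seq_id, ring_id).  Returns None when no candidate
    ring shares a model with the proton.
    """
    proton_by_model = {
        m.number: m.atoms[amide_key].coords for m in ensemble.models if amide_key in m.atoms
    }
    if not proton_by_model:
        return None
    best: RingAssignment | None = None
    for ring in rings:
        shared = sorted(set(proton_by_model) & set(ring.per_model))
        if not shared:
            continue
        dists: dict[int, float] = {}
        azis: list[float] = []
        for mnum in shared:
            center, normal = ring.per_model[mnum]
            p = proton_by_model[mnum]
            dists[mnum] = proton_ring_distance(p, center)
            try:
                azis.append(azimuth(p, center, normal))
            except UndefinedAzimuthError:
                azis.append(0.0)  # degenerate: proton at center, flagged by d=0
        avg_d = float(np.mean(list(dists.values())))
        cand = RingAssignment(
            amide_key=amide_key,
            ring=ring,
            avg_distance=avg_d,
            avg_azimuth=float(np.mean(azis)),
            per_model_distances=dists,
        )
        if best is None or avg_d < best.avg_distance - 1e-6:
            best = cand
        elif abs(avg_d - best.avg_distance) <= 1e-6 and ring.key < best.ring.key:
            best = cand
    return best
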