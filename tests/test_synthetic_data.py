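import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from amide_ring_miner import ring_geometry as rg
from amide_ring_miner import shift_io, structure_io
from amide_ring_miner import synthetic_data as sd
from amide_ring_miner.structure_io import AtomSite, Ensemble, Model
from amide_ring_miner.synthetic_data import InvalidConfigError, SyntheticConfig


def all_rings(ensemble):
    """(chain, seq, ring_id) -> member coordinate array per model."""
    member_sets = {
        "PHE": {"six": sd._SIX_MEMBERS}, "TYR": {"six": sd._SIX_MEMBERS},
        "HIS": {"five": sd._PENT_MEMBERS_HIS},
        "TRP": {"six": sd._TRP_SIX, "five": sd._TRP_FIVE},
    }
    out = {}
    for (chain, seq), rtype in ensemble.residue_types().items():
        for ring_id, members in member_sets.get(rtype, {}).items():
            for model in ensemble.models:
                pts = np.array([model.atoms[(chain, seq, a)].coords for a in members])
                out[(chain, seq, ring_id, model.number)] = pts
    return out


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_entries=0)
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_models=0)
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(aromatic_fraction=1.5)
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(restraint_cutoff=0.0)

    def test_chain_length_below_two_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(chain_length=1)


class TestGenerateStructure:
    def test_minimal_case(self):
        cfg = SyntheticConfig(n_models=1, chain_length=2, aromatic_fraction=0.0, seed=1)
        ens = sd.generate_structure(cfg, 0)
        assert len(ens.models) == 1
        amides = [k for k in ens.models[0].atoms if k[2] == "H"]
        assert len(amides) == 1
        assert all_rings(ens) == {}

    def test_roster_conserved_across_models(self):
        cfg = SyntheticConfig(n_models=3, chain_length=8, aromatic_fraction=0.5, seed=2)
        ens = sd.generate_structure(cfg, 0)
        rosters = {m.roster() for m in ens.models}
        assert len(rosters) == 1

    def test_models_differ_in_non_ring_atoms(self):
        cfg = SyntheticConfig(n_models=2, chain_length=5, aromatic_fraction=0.0, seed=3)
        ens = sd.generate_structure(cfg, 0)
        a0 = ens.models[0].atoms[("A", 2, "CA")]
        a1 = ens.models[1].atoms[("A", 2, "CA")]
        assert (a0.x, a0.y, a0.z) != (a1.x, a1.y, a1.z)

    def test_every_non_first_residue_has_amide_proton(self):
        cfg = SyntheticConfig(chain_length=10, aromatic_fraction=0.3, seed=4)
        ens = sd.generate_structure(cfg, 0)
        for seq in range(2, 11):
            assert ("A", seq, "H") in ens.models[0].atoms

    def test_hexagon_centroid_matches_anchor(self):
        cfg = SyntheticConfig(chain_length=20, aromatic_fraction=1.0, seed=5)
        ens = sd.generate_structure(cfg, 0)
        anchors = ens.meta["ring_anchors"]
        phe_keys = [
            k for k, rtype in ens.meta["residue_types"].items() if rtype == "PHE"
        ]
        assert phe_keys, "need at least one PHE in the fixture"
        for chain, seq in phe_keys:
            pts = np.array([
                ens.models[0].atoms[(chain, seq, a)].coords for a in sd._SIX_MEMBERS
            ])
            assert np.linalg.norm(pts.mean(axis=0) - anchors[(chain, seq, "six")]) < 1e-9

    def test_ring_planarity_and_bond_lengths(self):
        cfg = SyntheticConfig(n_models=3, chain_length=24, aromatic_fraction=1.0, seed=6)
        ens = sd.generate_structure(cfg, 0)
        for (chain, seq, ring_id, mnum), pts in all_rings(ens).items():
            center = pts.mean(axis=0)
            # best-fit plane via SVD: smallest singular direction
            _, s, _ = np.linalg.svd(pts - center)
            assert s[-1] < 1e-6  # vertex deviation from best plane
            n = len(pts)
            for i in range(n):
                bond = np.linalg.norm(pts[i] - pts[(i + 1) % n])
                assert bond == pytest.approx(1.39, abs=0.02)

    def test_trp_rings_share_fused_edge(self):
        cfg = SyntheticConfig(chain_length=30, aromatic_fraction=1.0, seed=7)
        ens = sd.generate_structure(cfg, 0)
        trp = [k for k, t in ens.meta["residue_types"].items() if t == "TRP"]
        assert trp
        chain, seq = trp[0]
        m = ens.models[0].atoms
        # CD2/CE2 belong to both rings; five-ring must also be planar with them
        five = np.array([m[(chain, seq, a)].coords for a in sd._TRP_FIVE])
        _, s, _ = np.linalg.svd(five - five.mean(axis=0))
        assert s[-1] < 1e-6


class TestRingCurrentDelta:
    def test_magic_angle_zero(self):
        assert sd.ring_current_delta(3.0, 54.7356, 1.0, 30.42) == pytest.approx(0.0, abs=1e-4)

    def test_on_axis_value(self):
        # direct evaluation: 1 * 30.42 * (1 - 3) / 27 = -2.253333...
        expected = 30.42 * (1 - 3 * math.cos(0.0) ** 2) / 3.0**3
        assert expected == pytest.approx(-2.2533, abs=5e-5)
        assert sd.ring_current_delta(3.0, 0.0, 1.0, 30.42) == pytest.approx(expected)

    def test_inverse_cube_scaling(self):
        d3 = sd.ring_current_delta(3.0, 0.0, 1.0, 30.42)
        d6 = sd.ring_current_delta(6.0, 0.0, 1.0, 30.42)
        assert d6 == pytest.approx(d3 / 8.0)

    def test_sign_convention(self):
        assert sd.ring_current_delta(3.0, 0.0, 1.0, 30.42) < 0  # axis: shielding
        assert sd.ring_current_delta(3.0, 90.0, 1.0, 30.42) > 0  # plane: deshielding

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            sd.ring_current_delta(0.0, 0.0, 1.0, 30.42)
        with pytest.raises(ValueError):
            sd.ring_current_delta(-1.0, 0.0, 1.0, 30.42)


def _axis_probe_ensemble(r=3.0):
    """One PHE ring in the z=0 plane plus one amide proton on its axis."""
    model = Model(number=1)
    for k, name in enumerate(sd._SIX_MEMBERS):
        ang = 2 * math.pi * k / 6
        model.add(AtomSite("A", 1, "PHE", name,
                           1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0))
    model.add(AtomSite("A", 2, "ALA", "H", 0.0, 0.0, r))
    return Ensemble(entry_id="T", models=[model])


class TestPlantShifts:
    def test_no_noise_no_rings_gives_exact_means(self, default_stats):
        cfg = SyntheticConfig(chain_length=6, aromatic_fraction=0.0,
                              noise_sd_scale=0.0, seed=8)
        ens = sd.generate_structure(cfg, 0)
        records, truth = sd.plant_shifts(ens, default_stats, cfg)
        for rec in records:
            assert rec.value == default_stats[(rec.residue_type, "H")].mean
        assert all(row.planted_delta == 0.0 for row in truth.rows)

    def test_on_axis_probe_shifted_by_ring_current(self, default_stats):
        cfg = SyntheticConfig(chain_length=2, noise_sd_scale=0.0, seed=9)
        ens = _axis_probe_ensemble(r=3.0)
        records, truth = sd.plant_shifts(ens, default_stats, cfg)
        (rec,) = records
        expected_delta = sd.ring_current_delta(3.0, 0.0, 1.0, cfg.effect_amplitude_B)
        assert rec.value == pytest.approx(
            default_stats[("ALA", "H")].mean + expected_delta, abs=1e-9
        )
        assert expected_delta == pytest.approx(-2.2533, abs=5e-5)
        assert truth.rows[0].planted_delta == pytest.approx(expected_delta)

    def test_same_seed_identical(self, default_stats):
        cfg = SyntheticConfig(chain_length=10, aromatic_fraction=0.4, seed=10)
        ens = sd.generate_structure(cfg, 0)
        r1, _ = sd.plant_shifts(ens, default_stats, cfg, seed=99)
        r2, _ = sd.plant_shifts(ens, default_stats, cfg, seed=99)
        assert r1 == r2

    def test_missing_residue_stats_raises_naming_type(self, default_stats):
        cfg = SyntheticConfig(chain_length=2, noise_sd_scale=0.0, seed=11)
        stats = {k: v for k, v in default_stats.items() if k[0] != "ALA"}
        ens = _axis_probe_ensemble()
        with pytest.raises(KeyError, match="ALA"):
            sd.plant_shifts(ens, stats, cfg)

    def test_zero_perturbation_outside_effect_radius(self, default_stats):
        cfg = SyntheticConfig(chain_length=2, noise_sd_scale=0.0, seed=12)
        ens = _axis_probe_ensemble(r=9.0)  # beyond the 8 A effect radius
        records, truth = sd.plant_shifts(ens, default_stats, cfg)
        assert records[0].value == default_stats[("ALA", "H")].mean
        assert truth.rows[0].planted_delta == 0.0
        assert truth.rows[0].ring_key is None


class TestPlantedSignInvariant:
    def test_axis_below_plane_above_mean(self, default_stats):
        cfg = SyntheticConfig(n_entries=4, chain_length=15, aromatic_fraction=0.5,
                              noise_sd_scale=0.0, probe_delta_sigma=4.0,
                              effect_amplitude_B=60.0, seed=13)
        n_axis = n_plane = 0
        for e in range(cfg.n_entries):
            ens = sd.generate_structure(cfg, e)
            records, truth = sd.plant_shifts(ens, default_stats, cfg)
            values = {(r.chain_id, r.seq_id): r.value for r in records}
            for row in truth.rows:
                if row.ring_key is None or row.avg_distance is None:
                    continue
                mean = default_stats[(row.residue_type, "H")].mean
                v = values[(row.chain_id, row.seq_id)]
                if row.avg_azimuth < 30 and row.avg_distance < 5 and row.ring_type != "HIS":
                    assert v < mean
                    n_axis += 1
                elif row.avg_azimuth > 80:
                    assert v > mean
                    n_plane += 1
        assert n_axis > 0 and n_plane > 0


class TestGenerateRestraints:
    def test_tiny_cutoff_empty(self):
        cfg = SyntheticConfig(chain_length=12, aromatic_fraction=0.5, seed=14)
        ens = sd.generate_structure(cfg, 0)
        assert sd.generate_restraints(ens, cutoff=0.1, seed=1) == []

    def test_single_close_pair(self):
        ens = _axis_probe_ensemble(r=3.0)
        # add ring protons so there is a restraint partner
        model = ens.models[0]
        for hname, parent in sd._RING_PROTON_PARENT["PHE"].items():
            p = model.atoms[("A", 1, parent)].coords
            model.add(AtomSite("A", 1, "PHE", hname, *(p * (2.41 / 1.39))))
        restraints = sd.generate_restraints(ens, cutoff=5.0, seed=1, decoy_fraction=0.0)
        close = [
            r for r in restraints
            if np.linalg.norm(
                model.atoms[r.member_1.atom_key].coords
                - model.atoms[r.member_2.atom_key].coords
            ) <= 5.0
        ]
        assert len(close) == len(restraints) > 0
        assert all(r.member_1.atom_name == "H" for r in restraints)

    def test_count_matches_brute_force(self):
        cfg = SyntheticConfig(n_entries=1, chain_length=15, aromatic_fraction=0.5,
                              probe_delta_sigma=4.0, effect_amplitude_B=60.0, seed=15)
        ens = sd.generate_structure(cfg, 0)
        cutoff = 5.0
        restraints = sd.generate_restraints(ens, cutoff, seed=1, decoy_fraction=0.0)
        # oracle: brute-force enumeration over all proton pairs
        rtypes = ens.residue_types()
        keys = sorted(ens.common_roster())
        expected = 0
        for a in keys:
            if a[2] != "H":
                continue
            for b in keys:
                if rtypes[b[:2]] not in rg.AROMATIC_TYPES:
                    continue
                if b[2] not in rg.ring_proton_names(rtypes[b[:2]]):
                    continue
                d = np.mean([
                    np.linalg.norm(m.atoms[a].coords - m.atoms[b].coords)
                    for m in ens.models
                ])
                if d <= cutoff:
                    expected += 1
        assert len(restraints) == expected > 0

    def test_decoys_present_and_rejectable(self):
        from amide_ring_miner.federate import classify_restraint
        cfg = SyntheticConfig(n_entries=1, chain_length=15, aromatic_fraction=0.5,
                              probe_delta_sigma=4.0, effect_amplitude_B=60.0, seed=16)
        ens = sd.generate_structure(cfg, 0)
        restraints = sd.generate_restraints(ens, 5.0, seed=1, decoy_fraction=0.2)
        decoys = [r for r in restraints if not classify_restraint(r)]
        assert decoys
        assert len(decoys) <= math.ceil(0.25 * len(restraints))


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestFixtureCorpus:
    def test_three_entries_layout(self, tmp_path):
        cfg = SyntheticConfig(n_entries=3, chain_length=6, seed=17)
        paths = sd.write_fixture_corpus(cfg, tmp_path / "c")
        assert len(paths.shift_files) == 3
        assert len(paths.structure_files) == 3
        import json
        mapping = json.loads(paths.mapping.read_text())
        assert len(mapping) == 3

    def test_round_trip_shift_values(self, small_corpus, small_config, default_stats):
        for e, path in enumerate(small_corpus.shift_files):
            ens = sd.generate_structure(small_config, e)
            expected, _ = sd.plant_shifts(
                ens, default_stats, small_config,
                seed=small_config.seed * 100003 + e,
                entry_id=sd.shift_entry_id(e),
            )
            got = shift_io.read_shift_records(path)
            assert len(got) == len(expected)
            for g, x in zip(got, expected):
                assert g.value == pytest.approx(x.value, abs=5e-4)
                assert (g.chain_id, g.seq_id, g.atom_name) == (x.chain_id, x.seq_id, x.atom_name)

    def test_round_trip_restraint_pairs(self, small_corpus, small_config):
        for e, path in enumerate(small_corpus.restraint_files):
            ens = sd.generate_structure(small_config, e)
            expected = sd.generate_restraints(
                ens, small_config.restraint_cutoff,
                seed=small_config.seed * 100003 + e,
                decoy_fraction=small_config.decoy_fraction,
                entry_id=sd.structure_entry_id(e),
            )
            got = shift_io.read_restraints(path)
            assert [(r.member_1, r.member_2) for r in got] == [
                (r.member_1, r.member_2) for r in expected
            ]

    def test_ground_truth_one_row_per_amide(self, small_corpus, small_config):
        gt = pd.read_csv(small_corpus.ground_truth, sep="\t")
        expected = small_config.n_entries * (small_config.chain_length - 1)
        assert len(gt) == expected

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_entries=2, chain_length=8, aromatic_fraction=0.5, seed=18)
        sd.write_fixture_corpus(cfg, tmp_path / "a")
        sd.write_fixture_corpus(cfg, tmp_path / "b")
        assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")

    def test_structures_round_trip(self, small_corpus):
        for path in small_corpus.structure_files:
            ens = structure_io.read_ensemble(path)
            assert len(ens.models) == 3
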