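import pytest

from amide_ring_miner import synthetic_data as sd
from amide_ring_miner.shift_io import ChemicalShiftRecord


def make_shift(entry="E1", chain="A", seq=1, res="ALA", atom="H", value=8.2, amb=None):
    return ChemicalShiftRecord(
        entry_id=entry, chain_id=chain, seq_id=seq, residue_type=res,
        atom_name=atom, value=value, ambiguity_code=amb,
    )


@pytest.fixture(scope="session")
def default_stats():
    return sd.default_reference_stats()


@pytest.fixture(scope="session")
def small_config():
    return sd.SyntheticConfig(
        n_entries=5, chain_length=12, aromatic_fraction=0.35, n_models=3,
        noise_sd_scale=1.0, effect_amplitude_B=60.0, probe_delta_sigma=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_corpus")
    return sd.write_fixture_corpus(small_config, out)
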