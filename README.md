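# amide-ring-miner

Federated mining of anomalous backbone amide ¹H chemical shifts near
aromatic rings.

The package joins three kinds of local input by atom identifiers
(chain id, sequence id, residue, atom):

- **assigned chemical shifts** and **distance restraints** in an
  NMR-STAR dialect (`shift_io`),
- **multi-model coordinate ensembles** in mmCIF (`structure_io`),
- an **entry-pair mapping** (shift-entry id ↔ structure-entry id, JSON).

For every amide proton with both a reported shift and coordinates it
computes a Z-score against filtered per-(residue, atom) reference
statistics (`shift_stats`), the ensemble-averaged distance and azimuth
to the center of the nearest aromatic ring of HIS/TRP/PHE/TYR
(`ring_geometry`), and whether the amide carries at least one restraint
to an aromatic ring proton (`federate`). The summaries (`outlier_analysis`)
report the fraction of restrained amides per Z-score bin, a per-type
distance/Z table under an 8 Å cutoff, and per-type upfield/downfield
direction counts.

A first-class synthetic-data module (`synthetic_data`) generates complete
toy corpora — planar rings with correct geometry, multi-model jitter,
restraints for close proton pairs, and amide shifts with a planted
point-dipole ring-current perturbation `i·B·(1−3cos²θ)/r³` — together
with a ground-truth sidecar, so the entire pipeline is testable offline
with known answers.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`: geometry closed-form and
brute-force oracles, statistics self-normalization and filter
bookkeeping, lossless corpus round trips, planted-effect recovery
(mean Z of ±4σ probe amides), monotonic restrained-fraction enrichment,
boundary conventions, and byte-level determinism.

## CLI

Generate a corpus and run the pipeline:

```sh
amide-ring-miner synth --out corpus/ --seed 1 --n-entries 10 --chain-length 20
amide-ring-miner run --corpus corpus/ --out results/ \
    --stats-table corpus/reference_stats.tsv --cutoff 8.0
```

`run` writes `merged.tsv`, `zbin_fractions.tsv`, `distance_z.tsv`,
`type_summary.tsv`, `run_report.tsv` and `run.log`. Without
`--stats-table`, reference statistics are computed from the corpus
itself (`--stats-mode full|filtered`; filtered applies the
aromatic/paramagnetic-ligand flags, the carbon-bound proton range rule
(>10 ppm or <−2.5 ppm, entry-level) and the strict eight-SD shift-level
drop).

Corpus layout: `shifts/<id>.str`, `restraints/<id>.str`,
`structures/<id>.cif`, `mapping.json` (JSON array of
`{"shift_id": ..., "structure_id": ...}`), plus `ground_truth.tsv` and
`reference_stats.tsv` for synthetic corpora.

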