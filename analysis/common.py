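"""Shared setup for the numbered analysis scripts: one deterministic
study-condition dataset, written under results/dataset on first use."""

from pathlib import Path

from chiptile import pipeline
from chiptile.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATASET = ROOT / "scratch" / "dataset"  # bulky simulated arrays; regenerated on demand

SEED = 1

# six permissive sites of graded affinity plus two high-affinity sites the
# chromatin does not permit (they should surface in the scan, not the calls)
PLANTED_SITES = [
    (15_000, 6.3e-8, True),
    (52_000, 1.0e-7, True),
    (88_000, 1.5e-7, True),
    (121_000, 8.0e-8, True),
    (150_000, 1.2e-7, True),
    (183_000, 6.3e-8, True),
    (70_000, 6.3e-8, False),
    (135_000, 1.0e-7, False),
]

CONFIG = SimConfig(seed=SEED, planted_sites=PLANTED_SITES)


def get_dataset() -> dict:
    """Simulate (once) and return the file map of the study dataset."""
    marker = DATASET / "planted_sites.tsv"
    if not marker.exists():
        pipeline.simulate_dataset(CONFIG, DATASET)
    names = ["genome", "annotation", "probe_map", "truth"] + [
        f"chip_rep{i}" for i in (1, 2, 3)
    ] + ["mock"]
    files = {
        "genome": DATASET / "genome.fa",
        "annotation": DATASET / "annotation.gff3",
        "probe_map": DATASET / "probes.bed",
        "truth": DATASET / "planted_sites.tsv",
        "mock": DATASET / "mock.tsv",
    }
    for i in (1, 2, 3):
        files[f"chip_rep{i}"] = DATASET / f"chip_rep{i}.tsv"
    assert all(p.exists() for p in files.values()), names
    return files


def analysis_config(files: dict, **extra) -> dict:
    cfg = {
        "genome_fasta": str(files["genome"]),
        "annotation_gff3": str(files["annotation"]),
        "chip_probe_tables": [str(files[f"chip_rep{i}"]) for i in (1, 2, 3)],
        "mock_probe_table": str(files["mock"]),
        "energy_matrix": str(pipeline._data_path("lrpb_energy_matrix.synthetic.tsv")),
        "seed": SEED,
    }
    cfg.update(extra)
    return cfg
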