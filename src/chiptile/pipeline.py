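"""End-to-end orchestration: simulate or load a dataset, call regions,
scan motifs, annotate, co-bind, and write every result table.

``run_pipeline`` is driven by a flat key/value config (YAML file or dict);
every analysis threshold is a named key with its conventional default
(log2 threshold 1, fold threshold 2, K_D threshold 14 uM, 200 bp upstream
windows, 500 bp region extension).  Identical configs produce identical
non-log outputs.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as _annotate
from . import cobind as _cobind
from . import io as _io
from . import motif as _motif
from . import peaks as _peaks
from . import simulate as _simulate

DEFAULTS = {
    "y0": 1.0,                 # log2-ratio calling threshold
    "fold_threshold": 2.0,     # per-replicate fold enrichment
    "kd_threshold": 14e-6,     # molar, motif-presence threshold
    "smoothing_half_width": 400,
    "upstream_window": 200,
    "extend_bp": 500,
    "min_probes": 3,
    "max_gap_bp": None,
    "circular": True,
    "seed": 0,
}


# ---------------------------------------------------------------------------
# bundled example data
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("chiptile").joinpath("data", name)))


def load_example_matrix() -> _io.EnergyPWM:
    """The bundled synthetic Lrp-box binding-energy matrix."""
    return _io.read_energy_matrix(_data_path("lrpb_energy_matrix.synthetic.tsv"))


def load_operator_boxes() -> dict[str, str]:
    """Characterized operator-box words bundled with the package."""
    df = pd.read_csv(_data_path("operator_boxes.tsv"), sep="\t", comment="#")
    return dict(zip(df["name"], df["sequence"]))


def load_cobound_table() -> pd.DataFrame:
    """Curated Ss-LrpB/LysM shared-binding-region survey."""
    df = pd.read_csv(_data_path("cobound_regions_sso.tsv"), sep="\t", comment="#")
    return df


def cobound_records_from_table(df: pd.DataFrame) -> list[_cobind.CoBindingRecord]:
    """Re-derive co-occupancy classes for a curated survey table.

    Motif flags are read from the table ('+' = present; a footnoted '-*'
    counts as absent, the raw string is kept in ``notes``).  In vitro flags
    follow the motif flags — the in-silico proxy appropriate for a survey
    whose direct-binding evidence mirrors motif presence.
    """
    records = []
    for row in df.itertuples(index=False):
        motif_a = str(row.lrpb_motif).startswith("+")
        motif_b = str(row.lysm_motif).startswith("+")
        rec = _cobind.CoBindingRecord(
            region_a=_io.Region("chr", int(row.peak_start), int(row.peak_stop), str(row.target)),
            region_b=_io.Region("chr", int(row.peak_start), int(row.peak_stop), "partner"),
            relation=str(row.relation),
            overlap_pct=int(row.overlap_pct) if pd.notna(row.overlap_pct) else 100,
            motif_a=motif_a,
            motif_b=motif_b,
            invitro_a=motif_a,
            invitro_b=motif_b,
            notes=f"lrpb={row.lrpb_motif};lysm={row.lysm_motif}",
        )
        _cobind.assign_class(rec)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# dataset simulation to disk
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: _simulate.SimConfig, outdir, pwm: _io.EnergyPWM | None = None
) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset.

    Emits genome FASTA, annotation GFF3, probe-map BED, one probe TSV per
    array (replicates + mock), and the planted-site truth TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pwm is None:
        pwm = load_example_matrix()
    import numpy as np

    rng = np.random.default_rng(config.seed)
    genome = _simulate.generate_genome(config)
    genome, planted = _simulate.plant_motifs(
        genome, pwm, config.planted_sites, protein_conc=config.protein_conc, rng=rng
    )
    scans = _simulate.simulate_chip(genome, planted, config)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    _io.write_fasta(genome, paths["genome"])
    paths["annotation"] = outdir / "annotation.gff3"
    _io.write_gff3(genome, paths["annotation"])
    probe_map = [
        _io.Region(genome.name, int(s), int(s) + config.probe_length, f"p{j:06d}")
        for j, s in enumerate(range(0, config.genome_length, config.probe_step))
    ]
    paths["probe_map"] = outdir / "probes.bed"
    _io.write_regions_bed(probe_map, paths["probe_map"])
    for scan in scans:
        p = outdir / f"{scan.sample_id}.tsv"
        _io.write_probe_table(scan, p)
        paths[scan.sample_id] = p
    paths["truth"] = outdir / "planted_sites.tsv"
    _simulate.write_truth_table(planted, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# the full analysis
# ---------------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = dict(DEFAULTS)
    merged.update(config or {})
    return merged


def run_pipeline(config, outdir=None) -> dict:
    """Run the whole analysis from a config file or dict; see module docs.

    Required keys: genome_fasta, annotation_gff3, chip_probe_tables (list),
    mock_probe_table, energy_matrix.  Optional: partner_regions_bed and
    energy_matrix_b for the co-occupancy stage.  Returns a dict of result
    objects and writes the result tables to ``outdir`` when given.
    """
    cfg = _load_config(config)
    problems = []
    for key in ("genome_fasta", "annotation_gff3", "mock_probe_table", "energy_matrix"):
        if key not in cfg:
            problems.append(f"missing config key: {key}")
        elif not Path(cfg[key]).exists():
            problems.append(f"input not found: {key} = {cfg[key]}")
    chip_tables = cfg.get("chip_probe_tables") or []
    if len(chip_tables) < 2:
        problems.append("chip_probe_tables must list at least 2 replicate tables")
    for p in chip_tables:
        if not Path(p).exists():
            problems.append(f"input not found: chip probe table {p}")
    for key in ("partner_regions_bed", "energy_matrix_b"):
        if cfg.get(key) and not Path(cfg[key]).exists():
            problems.append(f"input not found: {key} = {cfg[key]}")
    if problems:
        raise FileNotFoundError("; ".join(problems))

    genome = _io.read_fasta(cfg["genome_fasta"], circular=cfg["circular"])
    genes, tss = _io.read_gff3(cfg["annotation_gff3"])
    genome.genes, genome.tss = genes, tss
    genome.__post_init__()

    chip_scans = [_io.read_probe_table(p) for p in chip_tables]
    mock_scan = _io.read_probe_table(cfg["mock_probe_table"])
    chroms = {str(c) for s in chip_scans + [mock_scan] for c in s.probes["chrom"].unique()}
    if chroms != {genome.name}:
        raise ValueError(
            f"mixed chromosome names across inputs: genome {genome.name!r} vs probes {sorted(chroms)}"
        )

    hw = int(cfg["smoothing_half_width"])
    smoothed = [
        _peaks.smooth_scan(
            _peaks.normalize_scan(s), hw, genome_length=genome.length, circular=cfg["circular"]
        )
        for s in chip_scans
    ]
    mock_smoothed = _peaks.smooth_scan(
        _peaks.normalize_scan(mock_scan), hw, genome_length=genome.length, circular=cfg["circular"]
    )
    rep_regions = [
        _peaks.call_regions(s, y0=cfg["y0"], min_probes=cfg["min_probes"], max_gap_bp=cfg["max_gap_bp"])
        for s in smoothed
    ]
    combined = _peaks.combine_replicates(
        rep_regions, smoothed, mock_smoothed, fold_threshold=cfg["fold_threshold"], y0=cfg["y0"]
    )

    annotations = _annotate.annotate_regions(combined, genome)
    pwm = _io.read_energy_matrix(cfg["energy_matrix"])
    genome_hits = _motif.scan_sequence(pwm, genome, cfg["kd_threshold"])
    upstream = _motif.scan_upstream(
        pwm, genome, window_bp=int(cfg["upstream_window"]), kd_threshold=cfg["kd_threshold"]
    )
    region_flags = [
        _motif.motif_presence_flag(pwm, genome, r.as_region(), cfg["kd_threshold"])
        for r in combined
    ]

    cob_records: list[_cobind.CoBindingRecord] = []
    if cfg.get("partner_regions_bed"):
        partner = _io.read_regions_bed(cfg["partner_regions_bed"])
        regions_a = [r.as_region(f"region{i + 1}") for i, r in enumerate(combined)]
        cob_records = _cobind.overlap_regions(regions_a, partner, extend_bp=int(cfg["extend_bp"]))
        pwm_b = _io.read_energy_matrix(cfg["energy_matrix_b"]) if cfg.get("energy_matrix_b") else None
        for rec in cob_records:
            rec.motif_a = _motif.motif_presence_flag(pwm, genome, rec.region_a, cfg["kd_threshold"])
            rec.motif_b = (
                _motif.motif_presence_flag(pwm_b, genome, rec.region_b, cfg["kd_threshold"])
                if pwm_b is not None
                else False
            )
            rec.invitro_a, rec.invitro_b = rec.motif_a, rec.motif_b
            _cobind.assign_class(rec)

    results = {
        "config": cfg,
        "genome": genome,
        "regions": combined,
        "replicate_regions": rep_regions,
        "annotations": annotations,
        "category_counts": _annotate.category_counts(annotations),
        "genome_hits": genome_hits,
        "upstream": upstream,
        "region_motif_flags": region_flags,
        "cobinding": cob_records,
    }
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    combined = results["regions"]
    _io.write_regions_bed(
        [r.as_region(f"region{i + 1}") for i, r in enumerate(combined)],
        outdir / "regions.bed",
    )
    tbl = _annotate.annotation_table(results["annotations"])
    tbl["fold_enrichment"] = [r.fold_enrichment for r in combined]
    tbl["has_motif"] = results["region_motif_flags"]
    tbl.to_csv(outdir / "regions_annotated.tsv", sep="\t", index=False)
    with open(outdir / "motif_hits.bed", "w") as fh:
        for h in results["genome_hits"]:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.start + len(h.word)}\t{h.word}\t"
                f"{h.kd_theoretical:.3e}\t{h.strand}\n"
            )
    if results["cobinding"]:
        _cobind.cobinding_table(results["cobinding"]).to_csv(
            outdir / "cobinding.tsv", sep="\t", index=False
        )
    log = {
        "parameters": {
            k: results["config"][k]
            for k in sorted(DEFAULTS)
        },
        "n_regions": len(combined),
        "n_genome_hits": len(results["genome_hits"]),
        "n_upstream_hits": results["upstream"]["n_hits"],
        "category_counts": results["category_counts"],
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
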