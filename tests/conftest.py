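import numpy as np
import pandas as pd
import pytest

from chiptile import pipeline, simulate
from chiptile.io import ArrayScan, EnergyPWM, Gene, Genome, TSS


@pytest.fixture(scope="session")
def pwm() -> EnergyPWM:
    return pipeline.load_example_matrix()


@pytest.fixture(scope="session")
def boxes() -> dict:
    return pipeline.load_operator_boxes()


@pytest.fixture
def tiny_pwm() -> EnergyPWM:
    # width-3 matrix with hand-checkable energies; consensus ACG
    return EnergyPWM(
        energies=np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [1.5, 0.0, 0.5, 2.5],
                [2.0, 1.0, 0.0, 0.3],
            ]
        ),
        kd_consensus=1e-7,
    )


@pytest.fixture
def annotated_genome() -> Genome:
    """10 kb circular genome with two genes on opposite strands."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    genes = [Gene("gA", 1000, 2000, "+"), Gene("gB", 5000, 6200, "-")]
    tss = [TSS("gA", 960, "+"), TSS("gB", 6240, "-")]
    return Genome("chr", seq, circular=True, genes=genes, tss=tss)


def make_scan(values, step=25, probe_length=50, sample_id="s", role="chip-replicate"):
    """ArrayScan over uniformly spaced probes with the given (already
    duplicate-averaged) log2 ratios."""
    values = np.asarray(values, dtype=float)
    starts = np.arange(len(values)) * step
    df = pd.DataFrame(
        {
            "probe_id": [f"p{i:06d}" for i in range(len(values))],
            "chrom": "chr",
            "start": starts,
            "log2_ratio": values,
        }
    )
    return ArrayScan(sample_id=sample_id, role=role, probes=df, probe_length=probe_length)


@pytest.fixture
def make_uniform_scan():
    return make_scan


def recovery_run(seed: int, sites=None, noise_sd: float = 0.25):
    """One full simulate -> call cycle at study-scale defaults; returns
    (planted sites, combined regions, genome, config)."""
    if sites is None:
        sites = [
            (15_000, 6.3e-8, True),
            (52_000, 1.0e-7, True),
            (88_000, 1.5e-7, True),
            (121_000, 8e-8, True),
            (150_000, 1.2e-7, True),
            (183_000, 6.3e-8, True),
        ]
    cfg = simulate.SimConfig(seed=seed, noise_sd=noise_sd, planted_sites=sites)
    pwm_ = pipeline.load_example_matrix()
    genome = simulate.generate_genome(cfg)
    rng = np.random.default_rng(seed)
    genome, planted = simulate.plant_motifs(genome, pwm_, sites, rng=rng)
    scans = simulate.simulate_chip(genome, planted, cfg)
    from chiptile import peaks

    smoothed = [
        peaks.smooth_scan(peaks.normalize_scan(s), 400, genome_length=cfg.genome_length)
        for s in scans[: cfg.n_replicates]
    ]
    mock = peaks.smooth_scan(
        peaks.normalize_scan(scans[cfg.n_replicates]), 400, genome_length=cfg.genome_length
    )
    rep_regions = [peaks.call_regions(s) for s in smoothed]
    combined = peaks.combine_replicates(rep_regions, smoothed, mock)
    return planted, combined, genome, cfg
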