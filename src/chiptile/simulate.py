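"""Synthetic data generator for the whole analysis chain.

Emulates, at desk scale, the statistical structure of a genome-wide
occupancy study of an archaeal Lrp-family transcription factor: a small
circular genome with ORFs and TSSs, planted binding words of graded binding
energy, sonication-smeared ChIP enrichment over tiled probes with replicate
and mock noise, hyperbolic binding isotherms, and qPCR quantification-cycle
tables with planted fold changes.

Key modelling choices (see docs/methods.md):

* fragment smear = triangular kernel of half-width ``fragment_length``
  (default 500 bp), the simplest shape consistent with random sonication
  breakpoints; kernels wrap on the circular genome;
* a fully occupied site peaks at ``peak_log2_amplitude`` (default 2.5, i.e.
  5.7-fold, inside the 2.2-10.8 fold range such arrays report);
* occupancy of a planted site = P / (K_D + P) at a stated free protein
  concentration P; chromatin permissivity is a hard gate: non-permissive
  sites contribute zero signal regardless of affinity;
* the mock immunoprecipitation is pure probe noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ArrayScan, EnergyPWM, Gene, Genome, TSS, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    genome_length: int = 200_000
    gc_content: float = 0.5
    n_genes: int = 60
    probe_step: int = 25
    probe_length: int = 50
    fragment_length: int = 500
    n_replicates: int = 3
    noise_sd: float = 0.25          # log2-ratio units per probe
    peak_log2_amplitude: float = 2.5
    protein_conc: float = 1e-6      # molar, sets occupancy of planted sites
    planted_sites: list = field(default_factory=list)  # (position, target_kd, permissive)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 10 * self.fragment_length:
            raise ValueError("genome_length must exceed 10 x fragment_length")
        if self.probe_step > self.fragment_length / 2:
            raise ValueError("probe_step must be <= fragment_length / 2")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        for pos, _, _ in self.planted_sites:
            if not 0 <= pos < self.genome_length:
                raise ValueError(f"planted position {pos} outside genome")


@dataclass(frozen=True)
class PlantedSite:
    position: int        # 0-based center of the 15-mer
    strand: str
    word: str            # realized word (as written on its strand)
    target_kd: float     # requested, molar
    realized_kd: float   # K_D of the realized word, molar
    permissive: bool     # chromatin gate: False => no in vivo signal
    occupancy: float     # P / (K_D + P) in [0, 1]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig) -> Genome:
    """Random circular genome with non-overlapping ORFs and upstream TSSs.

    Bases are i.i.d. at the requested GC content.  ORF lengths are drawn
    around 900 bp; each gene gets a TSS 10-60 bp 5' of its start.  Refuses
    configurations whose total ORF length would exceed 80% of the genome.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(config.seed)
    p_gc = config.gc_content
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    seq = "".join(rng.choice(_BASES, size=config.genome_length, p=probs))

    lengths = rng.integers(600, 1200, size=config.n_genes)
    if lengths.sum() > 0.8 * config.genome_length:
        raise ValueError(
            f"cannot pack {config.n_genes} ORFs (total {lengths.sum()} bp) into "
            f"80% of a {config.genome_length} bp genome"
        )
    # lay genes left to right with random intergenic gaps
    spare = config.genome_length - int(lengths.sum())
    gaps = rng.dirichlet(np.ones(config.n_genes + 1)) * spare * 0.9
    genes: list[Gene] = []
    tss: list[TSS] = []
    cursor = 0
    for i, glen in enumerate(lengths):
        cursor += int(gaps[i])
        start, end = cursor, cursor + int(glen)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:04d}"
        genes.append(Gene(gid, start, end, strand))
        offset = int(rng.integers(10, 61))
        pos = (start - offset) % config.genome_length if strand == "+" else (end - 1 + offset) % config.genome_length
        tss.append(TSS(gid, pos, strand))
        cursor = end
    return Genome(name="synthchr", sequence=seq, circular=True, genes=genes, tss=tss)


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def _design_word(pwm: EnergyPWM, target_kd: float) -> tuple[str, float]:
    """Greedy mutation of the consensus toward a requested K_D.

    Accumulates single substitutions, at each step choosing the one whose
    resulting total energy is closest to the target energy without
    overshooting by more than ln(1.5).  Guaranteed within a factor 1.5 of
    ``target_kd`` when the matrix carries sub-0.4 kT penalties.
    """
    if target_kd < pwm.kd_consensus * (1 - 1e-9):
        raise ValueError(
            f"target K_D {target_kd:g} below the consensus K_D {pwm.kd_consensus:g}"
        )
    kd_max = pwm.kd_consensus * math.exp(pwm.max_energy)
    if target_kd > kd_max * 1.5:
        raise ValueError(
            f"target K_D {target_kd:g} unreachable; maximal attainable K_D is {kd_max:g}"
        )
    tol = math.log(1.5)
    eps_target = math.log(target_kd / pwm.kd_consensus)
    word = list(pwm.consensus)
    eps = 0.0
    bases = "ACGT"
    while eps_target - eps > tol:
        best = None  # (|gap after|, pos, base, new_eps)
        for i in range(pwm.width):
            current_pen = pwm.energies[i, bases.index(word[i])]
            for b in range(4):
                pen = pwm.energies[i, b]
                new_eps = eps - current_pen + pen
                if new_eps <= eps + 1e-12:  # must strictly increase energy
                    continue
                if new_eps > eps_target + tol:
                    continue
                gap = abs(new_eps - eps_target)
                cand = (gap, i, b, new_eps)
                if best is None or cand < best:
                    best = cand
        if best is None:
            raise ValueError(
                f"target K_D {target_kd:g} unreachable by greedy mutation; "
                f"maximal attainable K_D is {kd_max:g}"
            )
        _, i, b, eps = best
        word[i] = bases[b]
    realized = "".join(word)
    return realized, pwm.kd_consensus * math.exp(eps)


def plant_motifs(
    genome: Genome,
    pwm: EnergyPWM,
    sites: list[tuple[int, float, bool]],
    protein_conc: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> tuple[Genome, list[PlantedSite]]:
    """Write words of requested affinity into the genome.

    ``sites`` holds (center_position, target_kd, permissive) triples.  The
    word realizing each target K_D (within a factor 1.5) is written centered
    at the position, on a random strand; occupancy is P / (K_D + P).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    seq = list(genome.sequence)
    L = genome.length
    half = pwm.width // 2
    planted: list[PlantedSite] = []
    for position, target_kd, permissive in sites:
        word, realized_kd = _design_word(pwm, target_kd)
        strand = "+" if rng.random() < 0.5 else "-"
        written = word if strand == "+" else revcomp(word)
        start = (position - half) % L
        for j, base in enumerate(written):
            seq[(start + j) % L] = base
        planted.append(
            PlantedSite(
                position=position,
                strand=strand,
                word=word,
                target_kd=target_kd,
                realized_kd=realized_kd,
                permissive=bool(permissive),
                occupancy=protein_conc / (realized_kd + protein_conc),
            )
        )
    new_genome = Genome(
        name=genome.name,
        sequence="".join(seq),
        circular=genome.circular,
        genes=list(genome.genes),
        tss=list(genome.tss),
    )
    return new_genome, planted


def write_truth_table(sites: list[PlantedSite], path) -> None:
    pd.DataFrame(
        {
            "position": [s.position for s in sites],
            "strand": [s.strand for s in sites],
            "word": [s.word for s in sites],
            "target_kd": [s.target_kd for s in sites],
            "realized_kd": [s.realized_kd for s in sites],
            "permissive": [s.permissive for s in sites],
            "occupancy": [s.occupancy for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ChIP signal over tiled probes
# ---------------------------------------------------------------------------

def _true_signal(
    positions: np.ndarray, sites: list[PlantedSite], config: SimConfig
) -> np.ndarray:
    """Noise-free log2 enrichment per probe: sum of occupancy-scaled
    triangular kernels (half-width fragment_length, circular)."""
    L = config.genome_length
    hw = config.fragment_length
    signal = np.zeros(len(positions))
    for site in sites:
        if not site.permissive:
            continue
        d = np.abs(positions - site.position)
        d = np.minimum(d, L - d)  # circular distance
        kernel = np.clip(1.0 - d / hw, 0.0, None)
        signal += config.peak_log2_amplitude * site.occupancy * kernel
    return signal


def simulate_chip(
    genome: Genome, sites: list[PlantedSite], config: SimConfig
) -> list[ArrayScan]:
    """``n_replicates`` ChIP scans plus one mock, technical duplicates included.

    Observed log2 ratio = true signal + N(0, noise_sd), drawn independently
    per probe, per duplicate and per array; the mock array sees noise only.
    """
    rng = np.random.default_rng(config.seed + 1)
    starts = np.arange(0, config.genome_length, config.probe_step)
    centers = (starts + config.probe_length // 2) % config.genome_length
    truth = _true_signal(centers, sites, config)
    n = len(starts)
    scans: list[ArrayScan] = []
    roles = [("chip-replicate", f"chip_rep{i + 1}") for i in range(config.n_replicates)]
    roles.append(("mock", "mock"))
    for role, sample_id in roles:
        base = truth if role == "chip-replicate" else np.zeros(n)
        frames = []
        for dup in (1, 2):
            noise = rng.normal(0.0, config.noise_sd, size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"p{j:06d}" for j in range(n)],
                        "chrom": genome.name,
                        "start": starts,
                        "log2_ratio": base + noise,
                        "duplicate_index": dup,
                    }
                )
            )
        scans.append(
            ArrayScan(
                sample_id=sample_id,
                role=role,
                probes=pd.concat(frames, ignore_index=True),
                probe_length=config.probe_length,
            ).sorted()
        )
    return scans


# ---------------------------------------------------------------------------
# isotherms and Cq tables
# ---------------------------------------------------------------------------

def simulate_isotherm(
    kd: float,
    concentrations,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-site binding isotherm with additive noise on fraction bound."""
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("protein concentrations must be strictly positive")
    if not (np.diff(conc) > 0).all():
        raise ValueError("concentrations must be sorted ascending")
    rng = np.random.default_rng(seed)
    f = conc / (kd + conc) + rng.normal(0.0, noise_sd, size=conc.shape)
    return pd.DataFrame(
        {"protein_conc": conc, "fraction_bound": np.clip(f, 0.0, 1.0)}
    )


def simulate_cq_table(
    genes: list[str],
    fold_changes: list[float],
    ref_gene: str = "tbp",
    n_bioreps: int = 4,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy Cq table for WT and mutant strains with planted fold changes.

    A planted expression fold F for a gene shifts the mutant Cq by -log2(F)
    cycles relative to WT (more template -> earlier quantification cycle).
    The reference gene is always present with fold 1.
    """
    if len(genes) != len(fold_changes):
        raise ValueError("genes and fold_changes differ in length")
    rng = np.random.default_rng(seed)
    all_genes = list(genes)
    folds = {g: f for g, f in zip(genes, fold_changes)}
    if ref_gene not in folds:
        all_genes.append(ref_gene)
    folds[ref_gene] = 1.0
    base_cq = {g: float(rng.uniform(18.0, 26.0)) for g in all_genes}
    rows = []
    for strain in ("WT", "mutant"):
        for rep in range(1, n_bioreps + 1):
            for g in all_genes:
                shift = -math.log2(folds[g]) if strain == "mutant" else 0.0
                cq = base_cq[g] + shift + rng.normal(0.0, noise_sd)
                rows.append((g, strain, rep, cq))
    return pd.DataFrame(rows, columns=["gene_id", "strain", "biorep_id", "cq"])


def simulate_chip_qpcr(
    targets: list[str],
    enrichment_folds: list[float],
    ref_target: str = "spike",
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq table for ChIP-qPCR validation: (target, assay in {IP, input}, Cq).

    An enrichment fold F lowers the IP Cq of the target by log2(F) relative
    to input, on top of the spiked reference fragment (fold 1).
    """
    rng = np.random.default_rng(seed)
    all_targets = list(targets) + [ref_target]
    folds = dict(zip(targets, enrichment_folds))
    folds[ref_target] = 1.0
    rows = []
    for t in all_targets:
        base = float(rng.uniform(20.0, 28.0))
        rows.append((t, "input", base + rng.normal(0.0, noise_sd)))
        rows.append((t, "IP", base - math.log2(folds[t]) + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["target", "assay", "cq"])
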