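"""Binding-energy PWM scoring, theoretical K_D conversion and genome scanning.

The model: a word ``w`` of the matrix width has additive binding free energy
``eps(w) = sum_i E[i, w_i]`` in kT above the consensus, and a theoretical
dissociation constant ``K_D(w) = K_D_consensus * exp(eps(w))`` (a Boltzmann
factor anchored at the consensus affinity).  Any constant shift of the raw
matrix cancels in K_D ratios, so matrices are stored min-zero per position.

Both strands are always scanned; overlapping +/- hits at one locus are both
reported (real matrices are asymmetric even for palindromic consensi).
All threshold comparisons are inclusive (<=).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import EnergyPWM, Genome, Region, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int      # 0-based genomic start of the window
    strand: str     # '+' or '-'
    word: str       # genome slice, reverse-complemented for '-'
    energy: float   # kT above consensus
    kd_theoretical: float  # molar


def _encode(seq: str) -> np.ndarray:
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(idx.shape, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[idx == ord(base)] = code
    if (out < 0).any():
        pos = int(np.flatnonzero(out < 0)[0])
        raise ValueError(f"ambiguous/non-ACGT base {seq[pos]!r} at offset {pos}")
    return out


def score_word(pwm: EnergyPWM, word: str) -> float:
    """Additive binding free energy of ``word`` in kT above the consensus."""
    if len(word) != pwm.width:
        raise ValueError(f"word length {len(word)} != matrix width {pwm.width}")
    codes = _encode(word.upper())
    return float(pwm.energies[np.arange(pwm.width), codes].sum())


def kd_of_word(pwm: EnergyPWM, word: str) -> float:
    """Theoretical dissociation constant (molar) of ``word``."""
    return pwm.kd_consensus * math.exp(score_word(pwm, word))


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length words."""
    if len(a) != len(b):
        raise ValueError("words differ in length")
    return sum(x != y for x, y in zip(a, b))


def _window_energies(pwm: EnergyPWM, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Energies of all windows of ``codes`` on both strands.

    Returns (eps_plus, eps_minus), each of length len(codes) - width + 1,
    indexed by the window's leftmost (genomic) coordinate.
    """
    w = pwm.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    eps_p = np.zeros(n)
    eps_m = np.zeros(n)
    for j in range(w):
        col = codes[j : j + n]
        eps_p += pwm.energies[j, col]
        # minus-strand word read 3'->5' on the top strand: position j of the
        # motif aligns to top-strand offset (w-1-j), complemented
        eps_m += pwm.energies[j, 3 - codes[w - 1 - j : w - 1 - j + n]]
    return eps_p, eps_m


def scan_sequence(
    pwm: EnergyPWM, genome: Genome, kd_threshold: float
) -> list[MotifHit]:
    """All windows on both strands with theoretical K_D <= ``kd_threshold``.

    On circular genomes, origin-spanning windows are included; window start
    coordinates are reported mod genome length.
    """
    L = genome.length
    w = pwm.width
    if L < w:
        return []
    seq = genome.sequence + (genome.sequence[: w - 1] if genome.circular and L >= w else "")
    codes = _encode(seq)
    eps_p, eps_m = _window_energies(pwm, codes)
    eps_max = math.log(kd_threshold / pwm.kd_consensus)
    hits: list[MotifHit] = []
    for strand, eps in (("+", eps_p), ("-", eps_m)):
        for i in np.flatnonzero(eps <= eps_max + 1e-12):
            i = int(i)
            word = seq[i : i + w]
            hits.append(
                MotifHit(
                    chrom=genome.name,
                    start=i % L,
                    strand=strand,
                    word=word if strand == "+" else revcomp(word),
                    energy=float(eps[i]),
                    kd_theoretical=pwm.kd_consensus * math.exp(float(eps[i])),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_region(pwm: EnergyPWM, genome: Genome, region: Region) -> list[MotifHit]:
    """All windows (both strands, any K_D) fully inside ``region``.

    The region may span the origin of a circular genome (end > length is
    interpreted as wrapping); hit starts are reported mod genome length.
    """
    w = pwm.width
    if region.length < w:
        return []
    seq = genome.fetch_circular(region.start, region.length)
    codes = _encode(seq)
    eps_p, eps_m = _window_energies(pwm, codes)
    hits: list[MotifHit] = []
    for strand, eps in (("+", eps_p), ("-", eps_m)):
        for i in range(len(eps)):
            word = seq[i : i + w]
            hits.append(
                MotifHit(
                    chrom=genome.name,
                    start=(region.start + i) % genome.length,
                    strand=strand,
                    word=word if strand == "+" else revcomp(word),
                    energy=float(eps[i]),
                    kd_theoretical=pwm.kd_consensus * math.exp(float(eps[i])),
                )
            )
    return hits


def best_hit_in_region(
    pwm: EnergyPWM, genome: Genome, region: Region
) -> MotifHit | None:
    """Minimum-K_D window fully inside ``region``; ties broken by smaller
    start, then '+' strand.  None when the region is narrower than the motif."""
    hits = scan_region(pwm, genome, region)
    if not hits:
        return None
    offset = region.start  # rank by position within the region, not mod-L start
    return min(
        hits,
        key=lambda h: (
            h.energy,
            (h.start - offset) % genome.length,
            0 if h.strand == "+" else 1,
        ),
    )


def motif_presence_flag(
    pwm: EnergyPWM, genome: Genome, region: Region, kd_threshold: float
) -> bool:
    """True iff the region's best window has theoretical K_D <= threshold."""
    best = best_hit_in_region(pwm, genome, region)
    return best is not None and best.kd_theoretical <= kd_threshold * (1 + 1e-12)


def scan_upstream(
    pwm: EnergyPWM,
    genome: Genome,
    window_bp: int = 200,
    kd_threshold: float = 14e-6,
) -> dict[str, object]:
    """Scan the ``window_bp`` region 5' of every ORF start.

    For a '+' gene the window is [start - window_bp, start); for a '-' gene
    it is [end, end + window_bp).  Both strands are scanned within each
    window.  Returns per-gene hit lists, the per-gene minimum-K_D hit, and
    the number of genes with at least one hit under the threshold.
    """
    if not genome.genes:
        raise ValueError("genome has no gene annotation")
    per_gene_hits: dict[str, list[MotifHit]] = {}
    best: dict[str, MotifHit] = {}
    for gene in genome.genes:
        if gene.strand == "+":
            win = Region(genome.name, gene.start - window_bp, gene.start, gene.id)
        else:
            win = Region(genome.name, gene.end, gene.end + window_bp, gene.id)
        hits = [
            h
            for h in scan_region(pwm, genome, win)
            if h.kd_theoretical <= kd_threshold * (1 + 1e-12)
        ]
        per_gene_hits[gene.id] = hits
        if hits:
            best[gene.id] = min(hits, key=lambda h: (h.energy, h.start))
    return {
        "hits": per_gene_hits,
        "best": best,
        "n_genes_with_hit": len(best),
        "n_hits": sum(len(v) for v in per_gene_hits.values()),
    }
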