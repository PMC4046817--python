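"""Classify enriched regions by genomic context and distance to TSS.

Location categories (mutually exclusive, exhaustive):

* ``intergenic_only``            - overlaps intergenic sequence, no ORF
* ``intergenic_plus_one_orf``    - overlaps intergenic sequence and one ORF
* ``intergenic_plus_multiple_orfs`` - intergenic sequence and >= 2 ORFs
* ``intragenic_single``          - every base inside a single ORF
* ``intragenic_spanning``        - every base genic, >= 2 ORFs touched

The first three collapse to "overlaps intergenic" and the last two to
"exclusively intragenic" under the two-way summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import Genome, Region, TSS

CATEGORIES = (
    "intergenic_only",
    "intergenic_plus_one_orf",
    "intergenic_plus_multiple_orfs",
    "intragenic_single",
    "intragenic_spanning",
)


@dataclass(frozen=True)
class PeakAnnotation:
    region: Region
    location_category: str
    closest_gene_id: str
    tss_distance: int  # signed; negative = peak center 5' (upstream) of the gene


def _overlap_len(a0: int, a1: int, b0: int, b1: int, L: int, circular: bool) -> int:
    """Overlap of [a0,a1) with [b0,b1) on a genome of length L."""
    if not circular:
        return max(0, min(a1, b1) - max(a0, b0))
    # compare against the gene interval and its +-L images so regions that
    # wrap (end > L) are handled
    best = 0
    for shift in (-L, 0, L):
        best = max(best, max(0, min(a1, b1 + shift) - max(a0, b0 + shift)))
    return best


def classify_location(region: Region, genome: Genome) -> str:
    """Location category of a region with respect to the ORF annotation."""
    if not genome.genes:
        raise ValueError("genome carries no gene annotation")
    L = genome.length
    genic = 0
    n_orfs = 0
    # genic base count needs the union of gene overlaps; genes are
    # non-overlapping in this pipeline, so summing per-gene overlaps is exact
    for g in genome.genes:
        olap = _overlap_len(region.start, region.end, g.start, g.end, L, genome.circular)
        if olap > 0:
            n_orfs += 1
            genic += olap
    intergenic = region.length - genic
    if intergenic > 0:
        if n_orfs == 0:
            return "intergenic_only"
        if n_orfs == 1:
            return "intergenic_plus_one_orf"
        return "intergenic_plus_multiple_orfs"
    return "intragenic_single" if n_orfs == 1 else "intragenic_spanning"


def distance_to_tss(
    region: Region, tss_list: list[TSS], genome_length: int, circular: bool = True
) -> tuple[str, int]:
    """Closest TSS to the region center on the circle, with orientation sign.

    Distance is the minimal circular distance from the region's floor
    midpoint; the sign is negative when the center lies 5' (upstream) of the
    TSS with respect to the gene's strand.  Ties go to the TSS with the
    lower coordinate.
    """
    if not tss_list:
        raise ValueError("no TSS annotation supplied")
    center = region.center % genome_length
    best: tuple[int, int, str, int] | None = None  # (|d|, position, gene, signed)
    for t in sorted(tss_list, key=lambda t: t.position):
        raw = (center - t.position) % genome_length
        if circular and raw > genome_length / 2:
            delta = raw - genome_length
        elif not circular:
            delta = center - t.position
        else:
            delta = raw
        signed = delta if t.strand == "+" else -delta
        key = (abs(delta), t.position, t.gene_id, signed)
        if best is None or key[:2] < best[:2]:
            best = key
    return best[2], int(best[3])


def _closest_gene(region: Region, genome: Genome) -> str:
    L = genome.length
    center = region.center
    best = None
    for g in genome.genes:
        if g.start <= center < g.end:
            return g.id
        d = min(
            min((center - g.end) % L, (g.end - center) % L),
            min((center - g.start) % L, (g.start - center) % L),
        )
        if best is None or d < best[0]:
            best = (d, g.id)
    return best[1]


def annotate_regions(regions, genome: Genome) -> list[PeakAnnotation]:
    out = []
    for r in regions:
        reg = r.as_region() if hasattr(r, "as_region") else r
        gene_id, dist = distance_to_tss(reg, genome.tss, genome.length, genome.circular)
        out.append(
            PeakAnnotation(
                region=reg,
                location_category=classify_location(reg, genome),
                closest_gene_id=_closest_gene(reg, genome),
                tss_distance=dist,
            )
        )
    return out


def annotation_table(annotations: list[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.region.chrom for a in annotations],
            "start": [a.region.start for a in annotations],
            "end": [a.region.end for a in annotations],
            "location_category": [a.location_category for a in annotations],
            "closest_gene_id": [a.closest_gene_id for a in annotations],
            "tss_distance": [a.tss_distance for a in annotations],
        }
    )


def category_counts(annotations: list[PeakAnnotation]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.location_category] += 1
    return counts


def two_way_split(counts: dict[str, int]) -> dict[str, int]:
    """Collapse the five categories to intergenic-overlap vs intragenic-only."""
    intergenic = sum(counts[c] for c in CATEGORIES[:3])
    intragenic = sum(counts[c] for c in CATEGORIES[3:])
    return {"overlaps_intergenic": intergenic, "intragenic_only": intragenic}
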