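"""Co-occupancy analysis of two transcription factors' binding-region sets.

Region set A (the primary TF's ChIP-enriched regions) is extended by
``extend_bp`` on both ends; every pair with at least 1 bp of intersection
against set B (the partner TF's regions) yields a record carrying the
geometric relation and, once motif/in-vitro evidence is attached, a
co-occupancy class:

* class I   - A's motif present, A binds in vitro, B does not
* class II  - B's motif present, B binds in vitro, A does not
* class III - neither motif, neither binds in vitro
* otherwise ``unclassified`` (surfaced for review, never forced)

At gene level two further classes apply: IV (bound in vivo by A alone, no
partner) and V (bound by A in vitro only, with no in vivo signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import Region

CO_CLASSES = ("I", "II", "III", "unclassified")


@dataclass
class CoBindingRecord:
    region_a: Region          # extended primary-TF region
    region_b: Region          # partner-TF region
    relation: str             # 'inside' | 'including' | 'overlap'
    overlap_pct: int          # % of region_a covered, rounded, in (0, 100]
    motif_a: bool = False
    motif_b: bool = False
    invitro_a: bool = False
    invitro_b: bool = False
    co_class: str = "unclassified"
    notes: str = ""           # raw annotation (e.g. footnoted motif calls)


def overlap_regions(
    set_a: list[Region], set_b: list[Region], extend_bp: int = 500
) -> list[CoBindingRecord]:
    """All intersecting (extended A, B) pairs with relation and overlap %.

    ``inside``: extended A lies within B (identical regions count as
    inside); ``including``: B lies within extended A; otherwise ``overlap``
    with the percentage of extended A covered by B.
    """
    records: list[CoBindingRecord] = []
    for a in sorted(set_a, key=lambda r: r.start):
        ax = Region(a.chrom, a.start - extend_bp, a.end + extend_bp, a.name, a.score)
        for b in sorted(set_b, key=lambda r: r.start):
            s, e = max(ax.start, b.start), min(ax.end, b.end)
            if e <= s:
                continue
            inter = e - s
            if ax.start >= b.start and ax.end <= b.end:
                relation, pct = "inside", 100
            elif b.start >= ax.start and b.end <= ax.end:
                relation, pct = "including", round(100 * inter / ax.length)
            else:
                relation, pct = "overlap", round(100 * inter / ax.length)
            records.append(
                CoBindingRecord(region_a=ax, region_b=b, relation=relation, overlap_pct=pct)
            )
    return records


def assign_class(record: CoBindingRecord) -> str:
    """Co-occupancy class from the four evidence flags (see module docs)."""
    a_direct = record.motif_a and record.invitro_a and not record.invitro_b
    b_direct = record.motif_b and record.invitro_b and not record.invitro_a
    neither = not (record.motif_a or record.motif_b or record.invitro_a or record.invitro_b)
    if a_direct and not record.motif_b:
        cls = "I"
    elif b_direct and not record.motif_a:
        cls = "II"
    elif neither:
        cls = "III"
    else:
        cls = "unclassified"
    record.co_class = cls
    return cls


def gene_class(
    bound_in_vivo_a: bool,
    cobound_b: bool,
    invitro_only_a: bool,
    record: CoBindingRecord | None = None,
) -> str:
    """Gene-level class I-V.

    V: the region binds the primary TF in vitro but shows no in vivo signal.
    IV: bound in vivo by the primary TF alone (no partner co-occupancy).
    I-III: co-bound; delegated to :func:`assign_class` on the record.
    """
    if invitro_only_a and not bound_in_vivo_a:
        return "V"
    if bound_in_vivo_a and not cobound_b:
        return "IV"
    if bound_in_vivo_a and cobound_b:
        if record is None:
            return "unclassified"
        return assign_class(record)
    return "unclassified"


def cobinding_table(records: list[CoBindingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name_a": [r.region_a.name for r in records],
            "start_a": [r.region_a.start for r in records],
            "end_a": [r.region_a.end for r in records],
            "name_b": [r.region_b.name for r in records],
            "start_b": [r.region_b.start for r in records],
            "end_b": [r.region_b.end for r in records],
            "relation": [r.relation for r in records],
            "overlap_pct": [r.overlap_pct for r in records],
            "motif_a": [r.motif_a for r in records],
            "motif_b": [r.motif_b for r in records],
            "invitro_a": [r.invitro_a for r in records],
            "invitro_b": [r.invitro_b for r in records],
            "co_class": [r.co_class for r in records],
        }
    )
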