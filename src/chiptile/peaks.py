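"""Replicate-consistent, mock-filtered enriched-region calling.

Pipeline per array: average technical duplicates, median-center the log2
ratios, replace each probe value by the running median over a +-400 bp
window (wrapping on circular genomes), then take maximal runs of probes at
or above the log2 threshold y0 (default 1).  Candidate regions are the
intersection of the per-replicate calls; a candidate is retained only if
every replicate's maximum smoothed log2 ratio over it exceeds
log2(fold_threshold) (default fold 2) and the mock stays below y0 there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import ArrayScan, Region


@dataclass(frozen=True)
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    replicate_max_log2: tuple[float, ...]  # per-replicate max smoothed log2
    fold_enrichment: float                 # 2^(mean of per-replicate maxima)
    n_probes: int
    passed_mock_filter: bool

    @property
    def center(self) -> int:
        return (self.start + self.end - 1) // 2

    def as_region(self, name: str = ".") -> Region:
        return Region(self.chrom, self.start, self.end, name, self.fold_enrichment)


# ---------------------------------------------------------------------------
# normalization and smoothing
# ---------------------------------------------------------------------------

def normalize_scan(scan: ArrayScan) -> ArrayScan:
    """Average technical duplicates per probe, then median-center the array."""
    df = scan.probes
    if df["probe_id"].nunique() < 100:
        raise ValueError("refusing to normalize a scan with fewer than 100 probes")
    merged = (
        df.groupby(["probe_id", "chrom", "start"], as_index=False)["log2_ratio"]
        .mean()
        .sort_values(["start", "probe_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    med = float(merged["log2_ratio"].median())
    merged["log2_ratio"] = merged["log2_ratio"] - med
    if merged["log2_ratio"].abs().max() == 0.0:
        warnings.warn("all probe ratios identical; centered to zeros", stacklevel=2)
    return replace(scan, probes=merged)


def smooth_scan(
    scan: ArrayScan,
    half_width_bp: int = 400,
    genome_length: int | None = None,
    circular: bool = True,
) -> ArrayScan:
    """Running median over all probes within +-half_width_bp of each probe.

    ``genome_length`` enables wrap-around windows on circular genomes; when
    omitted the scan is treated as linear.
    """
    df = scan.probes.sort_values("start", kind="mergesort").reset_index(drop=True)
    pos = df["start"].to_numpy(dtype=np.int64)
    val = df["log2_ratio"].to_numpy(dtype=float)
    n = len(pos)
    if circular and genome_length is not None:
        # unwrap: append shifted copies so every window is contiguous
        ext_pos = np.concatenate([pos - genome_length, pos, pos + genome_length])
        ext_val = np.concatenate([val, val, val])
        base = n  # index offset of the central copy
    else:
        ext_pos, ext_val, base = pos, val, 0
    lo = np.searchsorted(ext_pos, pos - half_width_bp, side="left")
    hi = np.searchsorted(ext_pos, pos + half_width_bp, side="right")
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(ext_val[lo[i] : hi[i]])
    sm = df.copy()
    sm["log2_ratio"] = out
    return replace(scan, probes=sm)


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def call_regions(
    smoothed: ArrayScan,
    y0: float = 1.0,
    min_probes: int = 3,
    max_gap_bp: int | None = None,
) -> list[Region]:
    """Maximal runs of probes with smoothed log2 ratio >= y0.

    A run is a maximal set of passing probes in which consecutive passing
    probes are no more than ``max_gap_bp`` apart start-to-start (default:
    twice the median probe spacing, bridging one failed/missing probe).
    Runs shorter than ``min_probes`` passing probes are dropped.  Region
    span = first passing probe start to last passing probe end
    (start + probe_length).
    """
    df = smoothed.probes.sort_values("start", kind="mergesort").reset_index(drop=True)
    pos = df["start"].to_numpy(dtype=np.int64)
    val = df["log2_ratio"].to_numpy(dtype=float)
    if max_gap_bp is None:
        steps = np.diff(pos)
        step = int(np.median(steps)) if len(steps) else 1
        max_gap_bp = 2 * step
    chrom = str(df["chrom"].iloc[0]) if len(df) else "."
    regions: list[Region] = []
    run: list[int] = []
    for i in np.flatnonzero(val >= y0):
        i = int(i)
        if run and pos[i] - pos[run[-1]] > max_gap_bp:
            _flush_run(run, pos, smoothed.probe_length, min_probes, chrom, val, regions)
            run = []
        run.append(i)
    _flush_run(run, pos, smoothed.probe_length, min_probes, chrom, val, regions)
    return regions


def _flush_run(run, pos, probe_length, min_probes, chrom, val, regions) -> None:
    if len(run) >= min_probes:
        regions.append(
            Region(
                chrom,
                int(pos[run[0]]),
                int(pos[run[-1]]) + probe_length,
                name=f"region{len(regions) + 1}",
                score=float(np.max(val[run])),
            )
        )


def _max_over(scan: ArrayScan, start: int, end: int) -> float:
    """Maximum smoothed log2 ratio of probes starting within [start, end)."""
    df = scan.probes
    sel = (df["start"] >= start) & (df["start"] < end)
    if not sel.any():
        return float("-inf")
    return float(df.loc[sel, "log2_ratio"].max())


def _intersect_many(region_lists: list[list[Region]]) -> list[tuple[int, int]]:
    """Intersection of the span unions across all lists."""
    spans = [(r.start, r.end) for r in region_lists[0]]
    for regions in region_lists[1:]:
        other = sorted((r.start, r.end) for r in regions)
        nxt: list[tuple[int, int]] = []
        for a0, a1 in spans:
            for b0, b1 in other:
                s, e = max(a0, b0), min(a1, b1)
                if e > s:
                    nxt.append((s, e))
        spans = sorted(nxt)
    return spans


def combine_replicates(
    replicate_regions: list[list[Region]],
    replicate_scans: list[ArrayScan],
    mock_scan: ArrayScan,
    fold_threshold: float = 2.0,
    y0: float = 1.0,
) -> list[EnrichedRegion]:
    """Regions supported by ALL replicates and absent from the mock.

    A candidate interval (intersection of overlapping per-replicate calls)
    is retained iff every replicate's maximum smoothed log2 ratio over it
    exceeds log2(fold_threshold) and the mock maximum stays below y0.
    """
    if len(replicate_regions) == 0:
        raise ValueError("no replicates supplied")
    if len(replicate_regions) < 2:
        raise ValueError("replicate-consistent calling needs >= 2 replicates")
    if len(replicate_regions) != len(replicate_scans):
        raise ValueError("one smoothed scan required per replicate region list")
    if any(not regions for regions in replicate_regions):
        return []
    chrom = replicate_regions[0][0].chrom
    log2_fold = float(np.log2(fold_threshold))
    out: list[EnrichedRegion] = []
    for start, end in _intersect_many(replicate_regions):
        maxima = tuple(_max_over(s, start, end) for s in replicate_scans)
        mock_max = _max_over(mock_scan, start, end)
        passed_mock = mock_max < y0
        if all(m > log2_fold for m in maxima) and passed_mock:
            n_probes = int(
                (
                    (replicate_scans[0].probes["start"] >= start)
                    & (replicate_scans[0].probes["start"] < end)
                ).sum()
            )
            out.append(
                EnrichedRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    replicate_max_log2=maxima,
                    fold_enrichment=float(2.0 ** np.mean(maxima)),
                    n_probes=n_probes,
                    passed_mock_filter=passed_mock,
                )
            )
    return out


# ---------------------------------------------------------------------------
# qPCR validation of enrichment
# ---------------------------------------------------------------------------

def qpcr_enrichment(cq: pd.DataFrame, ref_target: str = "spike") -> pd.Series:
    """Per-target ChIP-qPCR enrichment folds, normalized to a spiked reference.

    ``cq`` columns: target, assay ('IP' | 'input'), cq.
    fold(t) = 2^[(Cq_input,t - Cq_IP,t) - (Cq_input,ref - Cq_IP,ref)].
    """
    table = cq.pivot_table(index="target", columns="assay", values="cq", aggfunc="mean")
    for col in ("IP", "input"):
        if col not in table.columns:
            raise ValueError(f"Cq table missing assay column {col!r}")
    missing = table[table.isna().any(axis=1)].index.tolist()
    if missing:
        raise ValueError(f"missing Cq cell(s) for target(s): {missing}")
    if ref_target not in table.index:
        raise ValueError(f"reference target {ref_target!r} absent from Cq table")
    dcq = table["input"] - table["IP"]
    folds = 2.0 ** (dcq - dcq[ref_target])
    return folds.drop(ref_target)


def validate_correlation(chip_folds, qpcr_folds) -> tuple[float, float]:
    """Spearman rank correlation between array and qPCR enrichment folds."""
    chip = np.asarray(chip_folds, dtype=float)
    qpcr = np.asarray(qpcr_folds, dtype=float)
    if chip.shape != qpcr.shape:
        raise ValueError("fold vectors must be paired")
    if len(chip) < 5:
        raise ValueError("need at least 5 paired folds")
    rho, p = stats.spearmanr(chip, qpcr)
    return float(rho), float(p)
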