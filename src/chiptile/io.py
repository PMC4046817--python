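"""Readers/writers for every file format the pipeline touches.

All interval arithmetic downstream of this module uses 0-based half-open
coordinates on a single named chromosome.  BED is native to that convention;
GFF3 (1-based, inclusive) is converted here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(word: str) -> str:
    """Reverse complement of an uppercase A/C/G/T string."""
    return word.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class TSS:
    gene_id: str
    position: int
    strand: str


@dataclass
class Genome:
    """A (by default circular) chromosome with ORF and TSS annotation.

    ``sequence`` is uppercase A/C/G/T.  Gene and TSS coordinates are 0-based;
    gene intervals are half-open.
    """

    name: str
    sequence: str
    circular: bool = True
    genes: list[Gene] = field(default_factory=list)
    tss: list[TSS] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set(_BASES):
            bad = sorted(set(self.sequence) - set(_BASES))
            raise ValueError(f"genome contains non-ACGT characters: {bad}")
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids are not unique")
        for g in self.genes:
            if not (0 <= g.start < g.end <= len(self.sequence)):
                raise ValueError(f"gene {g.id} outside genome: ({g.start},{g.end})")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin on circular genomes."""
        if end <= start:
            raise ValueError(f"empty/negative slice ({start},{end})")
        return self.fetch_circular(start, end - start)

    def fetch_circular(self, start: int, length: int) -> str:
        """``length`` bases starting at ``start`` (mod genome length)."""
        L = self.length
        if length > L:
            raise ValueError("requested slice longer than genome")
        s = start % L
        if s + length <= L:
            return self.sequence[s : s + length]
        if not self.circular:
            raise ValueError("origin-spanning slice on a linear genome")
        return self.sequence[s:] + self.sequence[: s + length - L]


@dataclass(frozen=True)
class Region:
    """Plain genomic interval, 0-based half-open (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/negative interval ({self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end - 1) // 2  # floor midpoint


@dataclass
class ArrayScan:
    """Per-probe log2 ratios of one tiling array channel pair.

    ``probes`` columns: probe_id, chrom, start, log2_ratio and (until
    technical duplicates are averaged) duplicate_index.
    """

    sample_id: str
    role: str  # 'chip-replicate' | 'mock' | 'input'
    probes: pd.DataFrame
    probe_length: int = 50

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "start", "log2_ratio"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")

    def sorted(self) -> "ArrayScan":
        df = self.probes.sort_values(["start", "probe_id"], kind="mergesort")
        return replace(self, probes=df.reset_index(drop=True))


@dataclass
class EnergyPWM:
    """Position-specific binding free-energy penalties in kT.

    ``energies[i, b]`` is the penalty for base ``ACGT[b]`` at motif position
    ``i`` relative to the consensus; each row's minimum is zero and the
    per-row argmin spells the consensus word.  ``kd_consensus`` anchors the
    Boltzmann conversion of energies to theoretical dissociation constants.
    """

    energies: np.ndarray  # (width, 4), columns A,C,G,T
    kd_consensus: float   # molar

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[1] != 4:
            raise ValueError("energy matrix must be width x 4 (A,C,G,T)")
        if self.kd_consensus <= 0:
            raise ValueError("kd_consensus must be positive")
        # normalize: each row's minimum defines the zero of that position
        self.energies = self.energies - self.energies.min(axis=1, keepdims=True)
        assert (self.energies >= 0).all()

    @property
    def width(self) -> int:
        return self.energies.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[j] for j in self.energies.argmin(axis=1))

    @property
    def max_energy(self) -> float:
        return float(self.energies.max(axis=1).sum())


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = True) -> Genome:
    """First record of a FASTA file as an (unannotated) Genome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return Genome(name=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_fasta(genome: Genome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_gff3(path) -> tuple[list[Gene], list[TSS]]:
    """ORFs (``gene`` features) and ``transcription_start_site`` features.

    GFF3 is 1-based inclusive; returned coordinates are 0-based half-open.
    """
    genes: list[Gene] = []
    tss: list[TSS] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            _, _, ftype, start_s, end_s, _, strand, _, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            if ftype == "gene":
                genes.append(Gene(attr.get("ID", f"gene{lineno}"), start1 - 1, end1, strand))
            elif ftype == "transcription_start_site":
                tss.append(TSS(attr.get("Parent", attr.get("ID", "")), start1 - 1, strand))
    return genes, tss


def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for g in genome.genes:
            fh.write(
                f"{genome.name}\tchiptile\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
        for t in genome.tss:
            fh.write(
                f"{genome.name}\tchiptile\ttranscription_start_site\t{t.position + 1}\t{t.position + 1}\t.\t{t.strand}\t.\tParent={t.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

def write_probe_table(scan: ArrayScan, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={scan.sample_id}\n")
        fh.write(f"# role={scan.role}\n")
        fh.write(f"# probe_length={scan.probe_length}\n")
        scan.probes.to_csv(fh, sep="\t", index=False)


def read_probe_table(path) -> ArrayScan:
    meta = {"sample_id": "unknown", "role": "chip-replicate", "probe_length": "50"}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype={"probe_id": str, "chrom": str})
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    if ratios.isna().any():
        row = int(np.flatnonzero(ratios.isna().to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric log2_ratio in data row {row + 1} "
            f"(probe {df['probe_id'].iloc[row]!r})"
        )
    df["log2_ratio"] = ratios.astype(float)
    df["start"] = df["start"].astype(int)
    return ArrayScan(
        sample_id=meta["sample_id"],
        role=meta["role"],
        probes=df,
        probe_length=int(meta["probe_length"]),
    ).sorted()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_regions_bed(regions, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\n")


def read_regions_bed(path) -> list[Region]:
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            regions.append(Region(fields[0], start, end, name, score))
    return regions


# ---------------------------------------------------------------------------
# binding-energy matrix
# ---------------------------------------------------------------------------

def read_energy_matrix(path) -> EnergyPWM:
    """TSV of per-position A/C/G/T penalties plus a ``# kd_consensus`` header.

    Rows are normalized so each position's minimum penalty is zero; the
    consensus is then spelled by the per-row argmin.  Widths other than 15
    are accepted (a generic-width scanner) but unusual for this motif family.
    """
    kd_consensus = None
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("kd_consensus"):
                kd_consensus = float(body.split(None, 1)[1].replace("=", "").strip())
    if kd_consensus is None:
        raise ValueError(f"{path}: missing '# kd_consensus <molar>' header line")
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    for col in _BASES:
        if col not in df.columns:
            raise ValueError(f"{path}: missing base column {col!r}")
    energies = df[list(_BASES)].to_numpy(dtype=float)
    if energies.shape[0] != 15:
        import warnings

        warnings.warn(
            f"energy matrix width {energies.shape[0]} != 15 (the canonical Lrp-box width)",
            stacklevel=2,
        )
    return EnergyPWM(energies=energies, kd_consensus=kd_consensus)


def write_energy_matrix(pwm: EnergyPWM, path) -> None:
    with open(path, "w") as fh:
        fh.write("# binding free-energy penalties in kT relative to consensus\n")
        fh.write(f"# kd_consensus\t{pwm.kd_consensus:g}\n")
        df = pd.DataFrame(pwm.energies, columns=list(_BASES))
        df.insert(0, "pos", np.arange(1, pwm.width + 1))
        df.to_csv(fh, sep="\t", index=False)
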