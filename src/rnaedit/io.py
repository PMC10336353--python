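"""Readers/writers for the standard formats the pipeline touches.

One internal coordinate convention is used everywhere: 0-based, half-open
intervals and 0-based positions.  GFF3 and VCF are 1-based inclusive on disk
and are converted at the I/O boundary; BED is already 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# coordinate conversions (pure, tiny, property-tested)

def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive (GFF3/VCF style) -> 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SampleSheet:
    """sample_id -> group label mapping with exactly two groups."""

    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = list(dict.fromkeys(self.groups.values()))  # first-appearance order
        if len(labels) != 2:
            raise ValueError(f"need exactly two group labels, got {labels}")
        self.labels = tuple(labels)  # labels[0] = reference, labels[1] = case

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    def require_min_per_group(self, n: int = 2) -> None:
        for lab in self.labels:
            k = len(self.samples_in(lab))
            if k < n:
                raise ValueError(f"group {lab!r} has {k} samples; need >= {n}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t")
        if not {"sample", "group"} <= set(df.columns):
            raise FormatError(f"{path}: sample sheet needs 'sample' and 'group' columns")
        return cls(dict(zip(df["sample"].astype(str), df["group"].astype(str))))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"sample": self.samples,
                      "group": [self.groups[s] for s in self.samples]}
                     ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED (0-based half-open; column 4 = name/family)

def read_bed(path: str | Path, genome: dict[str, str] | None = None) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            if genome is not None:
                _check_bounds(chrom, start, end, genome, path, lineno)
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def _check_bounds(chrom, start, end, genome, path, lineno):
    if chrom not in genome:
        raise FormatError(f"{path}:{lineno}: unknown chrom {chrom!r}")
    if not (0 <= start < end <= len(genome[chrom])):
        raise FormatError(
            f"{path}:{lineno}: interval {start}-{end} out of bounds for {chrom}")


# ---------------------------------------------------------------------------
# VCF (sites-only).  Positions converted to internal 0-based.

def read_vcf_positions(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read a sites-only VCF into a set of (chrom, pos0, ref, alt) tuples.

    Multi-allelic records contribute one tuple per ALT allele.  Used for the
    known-SNP (dbSNP-like) exclusion, which matches on exact allele.
    """
    out: set[tuple[str, int, str, str]] = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.add((rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


def write_vcf_sites(records: list[tuple[str, int, str, str]],
                    contigs: dict[str, int], path: str | Path) -> None:
    """Write (chrom, pos0, ref, alt) tuples as a minimal sites-only VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in sorted(records):
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# SAM (delegated to pysam; see pileup.AlignmentStore for the bulk loader)

@dataclass
class AlignedRead:
    """A parsed SAM record with its CIGAR walked into coordinate pairs."""

    name: str
    chrom: str
    pos: int                       # 0-based leftmost reference position
    cigar: list[tuple[int, int]]   # pysam op codes
    seq: str
    qual: list[int]
    is_reverse: bool
    aligned_pairs: list[tuple[int | None, int | None]]  # (query_pos, ref_pos)


def read_sam(path: str | Path, genome: dict[str, str] | None = None) -> list[AlignedRead]:
    """Read a SAM file into AlignedRead records (reference implementation).

    Intended for small inputs and tests; the pipeline's bulk path is
    pileup.load_alignments.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for r in af:
            if r.is_unmapped:
                continue
            if genome is not None and r.reference_name not in genome:
                raise FormatError(f"{path}: read {r.query_name} maps to unknown "
                                  f"chrom {r.reference_name!r}")
            out.append(AlignedRead(
                name=r.query_name,
                chrom=r.reference_name,
                pos=r.reference_start,
                cigar=list(r.cigartuples or ()),
                seq=r.query_sequence or "",
                qual=list(r.query_qualities or ()),
                is_reverse=r.is_reverse,
                aligned_pairs=list(r.get_aligned_pairs()),
            ))
    return out


# ---------------------------------------------------------------------------
# TSV

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)
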