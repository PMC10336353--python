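"""Gene models: transcripts with exons/CDS, junctions, and GFF3 round-trip.

Coordinates are internal 0-based half-open; GFF3 on disk is 1-based inclusive.
Biotypes are free strings; anything other than ``protein_coding`` is treated
as non-coding for consequence annotation.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .io import FormatError, internal_to_gff

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Transcript:
    tx_id: str
    chrom: str
    strand: str                      # '+' or '-'
    biotype: str
    exons: list[tuple[int, int]]     # genomic order, 0-based half-open
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons + self.cds:
            if s >= e:
                raise ValueError(f"{self.tx_id}: empty interval {s}-{e}")

    # -- structure ---------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def junctions(self) -> list[int]:
        """Genomic coordinates of exon-boundary bases flanking each intron.

        For every intron the last base of the upstream exon and the first base
        of the downstream exon are reported; splice-distance filtering measures
        to these exon-boundary bases.
        """
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.extend([e1 - 1, s2])
        return out

    def exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds)

    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    # -- coordinate maps ---------------------------------------------------
    def genomic_to_cds(self, pos: int) -> int:
        """Genomic position -> 0-based CDS (coding-strand) offset."""
        if not self.in_cds(pos):
            raise ValueError(f"{self.tx_id}: {pos} not in CDS")
        off = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos < e:
                    return off + (pos - s)
                off += e - s
        else:
            for s, e in reversed(self.cds):
                if s <= pos < e:
                    return off + (e - 1 - pos)
                off += e - s
        raise AssertionError("unreachable")

    def cds_to_genomic(self, cds_off: int) -> int:
        """0-based CDS offset -> genomic position (inverse of genomic_to_cds)."""
        if not 0 <= cds_off < self.cds_len():
            raise ValueError(f"{self.tx_id}: CDS offset {cds_off} out of range")
        if self.strand == "+":
            for s, e in self.cds:
                if cds_off < e - s:
                    return s + cds_off
                cds_off -= e - s
        else:
            for s, e in reversed(self.cds):
                if cds_off < e - s:
                    return e - 1 - cds_off
                cds_off -= e - s
        raise AssertionError("unreachable")

    def cds_sequence(self, genome: dict[str, str]) -> str:
        parts = [genome[self.chrom][s:e] for s, e in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) genomic intervals; empty for non-coding transcripts."""
        if not self.cds:
            return [], []
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        left, right = [], []
        for s, e in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo)))
            if e > cds_hi:
                right.append((max(s, cds_hi), e))
        return (left, right) if self.strand == "+" else (right, left)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[Transcript]
    name: str = ""

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    def junctions(self) -> list[int]:
        out: set[int] = set()
        for t in self.transcripts:
            out.update(t.junctions())
        return sorted(out)


# ---------------------------------------------------------------------------
# GFF3 I/O

def write_gff3(genes: list[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = internal_to_gff(g.start, g.end)
            fh.write(f"{g.chrom}\trnaedit\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};biotype={g.biotype};Name={g.name or g.gene_id}\n")
            for t in g.transcripts:
                ts, te = internal_to_gff(t.start, t.end)
                fh.write(f"{g.chrom}\trnaedit\ttranscript\t{ts}\t{te}\t.\t{g.strand}\t.\t"
                         f"ID={t.tx_id};Parent={g.gene_id};biotype={t.biotype}\n")
                for i, (s, e) in enumerate(t.exons, 1):
                    s1, e1 = internal_to_gff(s, e)
                    fh.write(f"{g.chrom}\trnaedit\texon\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                             f"ID={t.tx_id}.exon{i};Parent={t.tx_id}\n")
                for i, (s, e) in enumerate(t.cds, 1):
                    s1, e1 = internal_to_gff(s, e)
                    fh.write(f"{g.chrom}\trnaedit\tCDS\t{s1}\t{e1}\t.\t{g.strand}\t0\t"
                             f"ID={t.tx_id}.cds{i};Parent={t.tx_id}\n")


def read_gff3(path: str | Path, genome: dict[str, str] | None = None) -> list[Gene]:
    """Read a GFF3 file into Gene/Transcript models (via gffutils, in memory)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[Gene] = []
    for gf in db.features_of_type("gene"):
        transcripts = []
        for tf in db.children(gf, featuretype=("transcript", "mRNA")):
            exons = [(ex.start - 1, ex.end) for ex in db.children(tf, featuretype="exon")]
            cds = [(c.start - 1, c.end) for c in db.children(tf, featuretype="CDS")]
            if not exons:
                raise FormatError(f"{path}: transcript {tf.id} has no exons")
            biotype = tf.attributes.get("biotype", [gf.attributes.get("biotype", ["protein_coding"])[0]])[0]
            transcripts.append(Transcript(tf.id, gf.seqid, gf.strand, biotype, exons, cds))
        if not transcripts:
            continue
        if genome is not None:
            if gf.seqid not in genome:
                raise FormatError(f"{path}: gene {gf.id} on unknown chrom {gf.seqid!r}")
            if gf.end > len(genome[gf.seqid]):
                raise FormatError(f"{path}: gene {gf.id} extends past end of {gf.seqid}")
        genes.append(Gene(gf.id, gf.seqid, gf.strand,
                          gf.attributes.get("biotype", ["protein_coding"])[0],
                          transcripts,
                          name=gf.attributes.get("Name", [gf.id])[0]))
    return genes


def genes_by_id(genes: list[Gene]) -> dict[str, Gene]:
    return {g.gene_id: g for g in genes}
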