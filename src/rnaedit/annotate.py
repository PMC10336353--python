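"""Functional consequence and HGVS annotation of accepted editing sites.

Each site is evaluated against every transcript of its host gene(s) and the
most severe consequence is reported, with severity ranked

    stop_lost > missense > stop_retained > synonymous > 5'UTR > 3'UTR
    > non-coding exonic > intronic

Intronic consequences are split by transcript biotype into protein-coding vs
non-coding-transcript intronic.  For CDS sites the HGVS c. and p. strings are
computed on the coding strand with the standard codon table (single-letter
amino acids; a synonymous change is written ``p.X123=``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .filters import EditingSite
from .genes import Gene, Transcript, revcomp
from .io import GenomicInterval

CATEGORIES = ("stop_lost", "missense", "stop_retained", "synonymous",
              "five_prime_UTR", "three_prime_UTR",
              "noncoding_transcript_exonic", "protein_coding_intronic",
              "noncoding_transcript_intronic")
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Consequence:
    category: str
    transcript: str
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_protein_change(pos: int, transcript: Transcript,
                            genome: dict[str, str]) -> tuple[str, str]:
    """HGVS (c., p.) strings for an A>G edit at a genomic CDS position."""
    if transcript.cds_len() % 3 != 0:
        raise AnnotationError(f"{transcript.tx_id}: CDS length not divisible by 3")
    cds_off = transcript.genomic_to_cds(pos)        # 0-based
    seq = genome[transcript.chrom]
    ref_base = seq[pos] if transcript.strand == "+" else revcomp(seq[pos])
    if ref_base != "A":
        raise AnnotationError(
            f"{transcript.tx_id}: coding-strand base at c.{cds_off + 1} is "
            f"{ref_base}, expected A")
    codon_index = cds_off // 3            # 0-based codon number
    within = cds_off % 3
    codon = "".join(
        (seq[g] if transcript.strand == "+" else revcomp(seq[g]))
        for g in (transcript.cds_to_genomic(codon_index * 3 + k)
                  for k in range(3)))
    edited = codon[:within] + "G" + codon[within + 1:]
    ref_aa = _translate_codon(codon)
    alt_aa = _translate_codon(edited)
    hgvs_c = f"c.{cds_off + 1}A>G"
    if alt_aa == ref_aa:
        hgvs_p = f"p.{ref_aa}{codon_index + 1}="
    else:
        hgvs_p = f"p.{ref_aa}{codon_index + 1}{alt_aa}"
    return hgvs_c, hgvs_p


def hgvs_c_to_genomic(hgvs_c: str, transcript: Transcript) -> int:
    """Decode a ``c.<pos>A>G`` string back to the genomic position."""
    m = re.fullmatch(r"c\.(\d+)([ACGT])>([ACGT])", hgvs_c)
    if not m:
        raise AnnotationError(f"cannot parse {hgvs_c!r}")
    return transcript.cds_to_genomic(int(m.group(1)) - 1)


def _transcript_consequence(pos: int, t: Transcript,
                            genome: dict[str, str]) -> Consequence | None:
    if not (t.start <= pos < t.end):
        return None
    if not t.exonic(pos):
        # intronic split is by transcript biotype
        cat = ("protein_coding_intronic" if t.biotype == "protein_coding"
               else "noncoding_transcript_intronic")
        return Consequence(cat, t.tx_id)
    if t.biotype != "protein_coding" or not t.is_coding:
        return Consequence("noncoding_transcript_exonic", t.tx_id)
    if t.in_cds(pos):
        hgvs_c, hgvs_p = annotate_protein_change(pos, t, genome)
        ref_aa = hgvs_p[2]
        if ref_aa == "*":
            cat = "stop_retained" if hgvs_p.endswith("=") else "stop_lost"
        elif hgvs_p.endswith("="):
            cat = "synonymous"
        else:
            cat = "missense"
        return Consequence(cat, t.tx_id, hgvs_c, hgvs_p)
    utr5, utr3 = t.utr_intervals()
    if any(s <= pos < e for s, e in utr5):
        return Consequence("five_prime_UTR", t.tx_id)
    if any(s <= pos < e for s, e in utr3):
        return Consequence("three_prime_UTR", t.tx_id)
    raise AnnotationError(f"exonic position {pos} in {t.tx_id} is neither "
                          "CDS nor UTR")


def classify_consequence(site: EditingSite | tuple, genes_by_id: dict[str, Gene],
                         genome: dict[str, str]) -> Consequence:
    """Most-severe consequence of a site over all transcripts of its host
    gene(s)."""
    if isinstance(site, EditingSite):
        pos, gene_ids = site.pos, site.gene_ids
    else:
        pos, gene_ids = site
    consequences = []
    for gid in gene_ids:
        gene = genes_by_id[gid]
        for t in gene.transcripts:
            c = _transcript_consequence(pos, t, genome)
            if c is not None:
                consequences.append(c)
    if not consequences:
        raise AnnotationError(
            f"site at {pos} lies outside all transcripts of {gene_ids}")
    return min(consequences, key=lambda c: _SEVERITY[c.category])


# ---------------------------------------------------------------------------
# repeat-family overlap

def repeat_overlap_table(sites, repeats: list[GenomicInterval]
                         ) -> dict[str, int]:
    """Count sites per overlapping repeat family ("none" if no overlap)."""
    trees: dict[str, IntervalTree] = {}
    for iv in repeats:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    counts: dict[str, int] = {}
    for site in sites:
        chrom, pos = (site.chrom, site.pos) if isinstance(site, EditingSite) \
            else site
        tree = trees.get(chrom)
        hits = sorted(iv.data for iv in tree.overlap(pos, pos + 1)) if tree else []
        family = hits[0] if hits else "none"
        counts[family] = counts.get(family, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# table-level driver

def annotate_sites(sites: list[EditingSite], genes: list[Gene],
                   genome: dict[str, str],
                   repeats: list[GenomicInterval]) -> pd.DataFrame:
    """Annotated-site table: consequence category, transcript, HGVS, repeat
    family, joined with per-sample levels."""
    from .filters import sites_to_frame
    gid_map = {g.gene_id: g for g in genes}
    rows = []
    for s in sites:
        c = classify_consequence(s, gid_map, genome)
        fam = repeat_overlap_table([s], repeats)
        rows.append({"category": c.category, "transcript": c.transcript,
                     "hgvs_c": c.hgvs_c, "hgvs_p": c.hgvs_p,
                     "repeat_family": next(iter(fam))})
    base = sites_to_frame(sites)
    return pd.concat([base, pd.DataFrame(rows)], axis=1)
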