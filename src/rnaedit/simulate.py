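"""Synthetic dataset generator with planted truth.

Builds a toy genome with embedded homopolymer runs and repeat copies, gene
models on both strands, and per-sample aligned reads in which A-to-I editing
sites, germline SNPs and six classes of artifact candidates are planted at
known positions and levels.  The defaults emulate the study design the
pipeline targets: two groups (control vs form-deprivation myopia, FDM) of six
samples each, ~50x depth, editing levels on the few-percent scale, and an
ADAR-like sequence-context bias (G depleted at -1, enriched at +1).

Everything is a deterministic function of the configuration (including its
seed): the same ``SimConfig`` yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import Gene, Transcript, revcomp, write_gff3
from .io import (GenomicInterval, SampleSheet, write_bed, write_fasta,
                 write_vcf_sites)

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES
                      if a + b + c not in _STOPS and a + b + c != "ATG")

TRUTH_CLASSES = ("editing_null", "editing_dre", "snp_het", "snp_hom",
                 "artifact_splice", "artifact_homopolymer", "artifact_repeat",
                 "artifact_readend", "artifact_indel", "artifact_chrM")
ARTIFACT_CLASSES = tuple(c for c in TRUTH_CLASSES if c.startswith("artifact"))

# first-fail filter name expected for each planted non-editing class
EXPECTED_REMOVAL_REASON = {
    "artifact_chrM": "chrM",
    "artifact_homopolymer": "homopolymer",
    "artifact_repeat": "simple_repeat",
    "artifact_splice": "splice",
    "artifact_indel": "indel",
    "artifact_readend": "read_end",
    "snp_het": "dbsnp",
    "snp_hom": "dbsnp",
}


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_per_group: int = 6
    group_labels: tuple[str, str] = ("control", "FDM")
    n_chroms: int = 3
    chrom_lengths: tuple[int, ...] = (32000, 32000, 32000)
    include_chrM: bool = True
    chrM_length: int = 3000
    n_genes: int = 42
    mean_depth: float = 50.0
    read_length: int = 100
    base_error_rate: float = 0.002
    base_qual_high: int = 38
    base_qual_low: int = 15
    low_qual_frac: float = 0.10
    n_null_edit_sites: int = 500
    n_dre_sites: int = 50
    n_snp_sites: int = 50
    n_artifact_sites: int = 60
    null_level_range: tuple[float, float] = (0.02, 0.30)
    control_level_range: tuple[float, float] = (0.05, 0.05)
    fdm_level_range: tuple[float, float] = (0.20, 0.20)
    artifact_level: float = 0.20
    adar_motif_bias: float = 2.0
    known_edit_frac: float = 0.25
    min_site_separation: int = 12

    def __post_init__(self):
        if len(self.chrom_lengths) != self.n_chroms:
            raise SimulationError(
                f"chrom_lengths has {len(self.chrom_lengths)} entries "
                f"but n_chroms={self.n_chroms}")
        if any(L <= 10 * self.read_length for L in self.chrom_lengths):
            raise SimulationError("every chrom must exceed 10x read_length")
        if self.n_per_group < 2:
            raise SimulationError("n_per_group must be >= 2")
        for rng_ in (self.null_level_range, self.control_level_range,
                     self.fdm_level_range):
            lo, hi = rng_
            if not (0 <= lo <= hi <= 1):
                raise SimulationError(f"level range {rng_} not within [0,1]")
        if not 0 <= self.base_error_rate <= 1:
            raise SimulationError("base_error_rate must be in [0,1]")
        if self.adar_motif_bias < 1:
            raise SimulationError("adar_motif_bias must be >= 1")

    @property
    def chrom_names(self) -> list[str]:
        names = [f"chr{i + 1}" for i in range(self.n_chroms)]
        if self.include_chrM:
            names.append("chrM")
        return names

    @property
    def sample_ids(self) -> list[str]:
        return [f"{lab}_{k + 1:02d}" for lab in self.group_labels
                for k in range(self.n_per_group)]

    def sample_sheet(self) -> SampleSheet:
        return SampleSheet({f"{lab}_{k + 1:02d}": lab
                            for lab in self.group_labels
                            for k in range(self.n_per_group)})


@dataclass
class TruthRecord:
    chrom: str
    pos: int            # 0-based internal
    strand: str         # strand of host gene
    cls: str
    level_control: float
    level_fdm: float
    gene_id: str = ""
    region: str = ""

    def __post_init__(self):
        if self.cls not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.cls!r}")
        if self.cls == "editing_dre" and self.level_control == self.level_fdm:
            raise ValueError("editing_dre must have unequal group levels")


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def by_class(self, cls: str) -> list[TruthRecord]:
        return [r for r in self.records if r.cls == cls]

    @property
    def editing_records(self) -> list[TruthRecord]:
        return [r for r in self.records if r.cls.startswith("editing")]

    def positions(self) -> set[tuple[str, int]]:
        return {(r.chrom, r.pos) for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chrom": r.chrom, "pos": r.pos + 1, "strand": r.strand,
            "class": r.cls, "level_control": r.level_control,
            "level_fdm": r.level_fdm, "gene": r.gene_id, "region": r.region,
        } for r in self.records])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls([TruthRecord(r.chrom, int(r.pos) - 1, r.strand, r["class"],
                                float(r.level_control), float(r.level_fdm),
                                str(r.gene), str(r.region))
                    for _, r in df.iterrows()])


# ---------------------------------------------------------------------------
# run-constrained random sequence

def _trailing_run(s: str) -> tuple[str, int]:
    if not s:
        return "", 0
    b, n = s[-1], 1
    while n < len(s) and s[-1 - n] == b:
        n += 1
    return b, n


def _free_seq(rng: np.random.Generator, n: int, ctx: str = "",
              max_run: int = 4) -> str:
    """Random sequence with no homopolymer run > max_run, given left context."""
    if n <= 0:
        return ""
    run_base, run_len = _trailing_run(ctx[-max_run:])
    picks = rng.integers(0, 4, size=n)
    alts = rng.integers(0, 3, size=n)
    out = []
    for i in range(n):
        b = BASES[picks[i]]
        if run_len >= max_run and b == run_base:
            b = [x for x in BASES if x != run_base][alts[i]]
        if b == run_base:
            run_len += 1
        else:
            run_base, run_len = b, 1
        out.append(b)
    return "".join(out)


def _has_long_run(s: str, max_run: int = 4) -> bool:
    b, n = "", 0
    for ch in s:
        n = n + 1 if ch == b else 1
        b = ch
        if n > max_run:
            return True
    return False


def _fix_boundary(left: str, right: str, max_run: int = 4) -> str:
    """Return left, possibly with its last base changed so that no run > max_run
    crosses the left|right boundary."""
    if not left or not right:
        return left
    window = left[-(max_run + 1):] + right[:max_run + 1]
    if not _has_long_run(window, max_run):
        return left
    for b in BASES:
        cand = left[:-1] + b
        if not _has_long_run(cand[-(max_run + 1):] + right[:max_run + 1], max_run):
            return cand
    raise AssertionError("no boundary-safe base found")  # impossible with 4 letters


# ---------------------------------------------------------------------------
# gene construction

@dataclass
class _EmbedSpec:
    kind: str          # homopolymer | simple_repeat | B1 | B2
    seq: str
    label: str         # track family label or run base


def _make_cds(rng: np.random.Generator, n_internal: int, ctx: str) -> str:
    """ATG + internal sense codons + stop, free of runs > 4 and internal stops."""
    for _ in range(100):
        parts = ["ATG"]
        tail = (ctx + "ATG")[-4:]
        ok = True
        for _ in range(n_internal):
            placed = False
            for _ in range(50):
                codon = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
                if not _has_long_run(tail + codon):
                    parts.append(codon)
                    tail = (tail + codon)[-4:]
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        stops = [s for s in _STOPS if not _has_long_run(tail + s)]
        if not stops:
            continue
        parts.append(stops[rng.integers(0, len(stops))])
        cds = "".join(parts)
        if not _has_long_run(cds):
            return cds
    raise SimulationError("could not build a run-free CDS")


def _split_exons(rng: np.random.Generator, total: int, n_exons: int,
                 min_exon: int = 60) -> list[int]:
    """Cut points (exclusive of 0 and total) splitting [0,total) into exons."""
    for _ in range(200):
        cuts = sorted(rng.integers(min_exon, total - min_exon + 1,
                                   size=n_exons - 1).tolist())
        sizes = np.diff([0] + cuts + [total])
        if (sizes >= min_exon).all() and len(set(cuts)) == n_exons - 1:
            return cuts
    raise SimulationError("could not split exons")


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    biotype: str
    mrna_exons: list[str]          # exon sequences in mRNA (5'->3') order
    utr5_len: int
    cds_len: int
    intron_specs: list[tuple[int, _EmbedSpec | None]]  # genomic order


def _plan_gene(rng: np.random.Generator, gene_id: str, strand: str,
               biotype: str, b1_seq: str, b2_seq: str) -> _GenePlan:
    if biotype == "protein_coding":
        utr5_len = 40
        n_internal = int(rng.integers(100, 181))
        utr3_len = 250
        utr5 = _free_seq(rng, utr5_len)
        cds = _make_cds(rng, n_internal, utr5[-4:])
        utr5 = _fix_boundary(utr5, cds)
        utr3 = _free_seq(rng, utr3_len, ctx=(utr5 + cds)[-4:])
        mrna = utr5 + cds + utr3
        cds_len = len(cds)
    else:
        utr5_len = 0
        cds_len = 0
        mrna = _free_seq(rng, int(rng.integers(400, 701)))
    n_exons = int(rng.integers(3, 6)) if biotype == "protein_coding" \
        else int(rng.integers(2, 4))
    cuts = _split_exons(rng, len(mrna), n_exons)
    bounds = [0] + cuts + [len(mrna)]
    mrna_exons = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]

    intron_specs: list[tuple[int, _EmbedSpec | None]] = []
    for _ in range(n_exons - 1):
        length = int(rng.integers(150, 401))
        u = rng.random()
        embed: _EmbedSpec | None = None
        if u < 0.22 and length >= len(b1_seq) + 60:
            if rng.random() < 0.8:
                embed = _EmbedSpec("repeat", b1_seq, "B1")
            else:
                embed = _EmbedSpec("repeat", b2_seq, "B2")
        elif u < 0.42 and length >= 90:
            unit = "CA" if strand == "+" else "TG"
            embed = _EmbedSpec("simple_repeat", unit * 12, "simple_repeat")
        elif u < 0.68 and length >= 60:
            if rng.random() < 0.75:
                base = "A" if strand == "+" else "T"
            else:
                base = BASES[rng.integers(0, 4)]
            embed = _EmbedSpec("homopolymer", base * int(rng.integers(5, 9)), base)
        intron_specs.append((length, embed))
    return _GenePlan(gene_id, strand, biotype, mrna_exons, utr5_len,
                     cds_len, intron_specs)


# ---------------------------------------------------------------------------
# genome assembly

@dataclass
class GenomeBuild:
    config: SimConfig
    genome: dict[str, str]
    genes: list[Gene]
    repeats: list[GenomicInterval]       # family-labelled (B1/B2/simple_repeat)
    homopolymers: list[GenomicInterval]  # name = run base

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    @classmethod
    def from_config(cls, config: SimConfig) -> "GenomeBuild":
        return _build_genome(config)


class _ChromAssembler:
    def __init__(self, chrom: str, rng: np.random.Generator):
        self.chrom = chrom
        self.rng = rng
        self.parts: list[str] = []
        self.cursor = 0

    @property
    def tail(self) -> str:
        t = ""
        for p in reversed(self.parts):
            t = p[-(5 - len(t)):] + t
            if len(t) >= 5:
                break
        return t

    def append_free(self, length: int) -> int:
        start = self.cursor
        self.parts.append(_free_seq(self.rng, length, ctx=self.tail))
        self.cursor += length
        return start

    def append_fixed(self, seq: str) -> int:
        if self.parts:
            fixed = _fix_boundary(self.tail, seq)
            if fixed != self.tail:
                last = self.parts[-1]
                self.parts[-1] = last[:-1] + fixed[-1]
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return start

    def sequence(self) -> str:
        return "".join(self.parts)


def _append_intron(asm: _ChromAssembler, length: int, embed: _EmbedSpec | None,
                   records: list[tuple[str, int, int, str]]) -> tuple[int, int]:
    """Append one intron; returns its (start, end). Embeds recorded absolutely."""
    start = asm.cursor
    if embed is None:
        asm.append_free(length)
        return start, start + length
    left = (length - len(embed.seq)) // 2
    right = length - len(embed.seq) - left
    asm.append_free(left)
    if embed.kind == "homopolymer":
        # keep the recorded run exact: flanks must differ from the run base
        base = embed.seq[0]
        tail = asm.tail
        if tail and tail[-1] == base:
            prev = asm.parts[-1]
            repl = [b for b in BASES if b != base and (len(tail) < 2 or b != tail[-2])][0]
            asm.parts[-1] = prev[:-1] + repl
        estart = asm.cursor
        asm.parts.append(embed.seq)
        asm.cursor += len(embed.seq)
        # right flank: context of >=4 copies of the run base forbids extension
        seq_r = _free_seq(asm.rng, right, ctx=base * 4)
        asm.parts.append(seq_r)
        asm.cursor += right
        records.append((embed.kind, estart, estart + len(embed.seq), embed.label))
    else:
        estart = asm.append_fixed(embed.seq)
        asm.append_free(right)
        records.append((embed.kind, estart, estart + len(embed.seq), embed.label))
    return start, asm.cursor


def _assemble_gene(asm: _ChromAssembler, plan: _GenePlan,
                   embed_records: list) -> Gene:
    n_exons = len(plan.mrna_exons)
    if plan.strand == "+":
        genomic_exon_seqs = plan.mrna_exons
    else:
        genomic_exon_seqs = [revcomp(s) for s in reversed(plan.mrna_exons)]
    exon_ivals: list[tuple[int, int]] = []
    for i, eseq in enumerate(genomic_exon_seqs):
        s = asm.append_fixed(eseq)
        exon_ivals.append((s, s + len(eseq)))
        if i < n_exons - 1:
            length, embed = plan.intron_specs[i]
            _append_intron(asm, length, embed, embed_records)
    # map mRNA-order exons to genomic intervals
    if plan.strand == "+":
        mrna_order_ivals = exon_ivals
    else:
        mrna_order_ivals = list(reversed(exon_ivals))
    cds_ivals: list[tuple[int, int]] = []
    if plan.cds_len:
        moff = 0
        a, b = plan.utr5_len, plan.utr5_len + plan.cds_len  # CDS in mRNA coords
        for seq, (gs, ge) in zip(plan.mrna_exons, mrna_order_ivals):
            mstart, mend = moff, moff + len(seq)
            lo, hi = max(a, mstart), min(b, mend)
            if lo < hi:
                if plan.strand == "+":
                    cds_ivals.append((gs + (lo - mstart), gs + (hi - mstart)))
                else:
                    cds_ivals.append((gs + (mend - hi), gs + (mend - lo)))
            moff = mend
    tx = Transcript(plan.gene_id + ".t1", asm.chrom, plan.strand,
                    plan.biotype, sorted(exon_ivals), sorted(cds_ivals))
    return Gene(plan.gene_id, asm.chrom, plan.strand, plan.biotype, [tx])


def _build_genome(config: SimConfig) -> GenomeBuild:
    rng = np.random.default_rng([config.seed, 1])
    b1_seq = _free_seq(rng, 150)
    b2_seq = _free_seq(rng, 120)
    genome: dict[str, str] = {}
    genes: list[Gene] = []
    repeats: list[GenomicInterval] = []
    homopolymers: list[GenomicInterval] = []

    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    gene_no = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_lengths[ci]
        for attempt in range(5):
            asm = _ChromAssembler(chrom, np.random.default_rng(
                [config.seed, 1, ci, attempt]))
            embed_records: list[tuple[str, int, int, str]] = []
            chrom_genes: list[Gene] = []
            ok = True
            for gi in range(per_chrom[ci]):
                strand = "+" if (gene_no + gi) % 2 == 0 else "-"
                biotype = "protein_coding" if asm.rng.random() > 0.12 else "lincRNA"
                plan = _plan_gene(asm.rng, f"gene{ci + 1:02d}{gi + 1:02d}",
                                  strand, biotype, b1_seq, b2_seq)
                span = sum(len(s) for s in plan.mrna_exons) + \
                    sum(length for length, _ in plan.intron_specs)
                spacer = int(asm.rng.integers(100, 161))
                if asm.cursor + spacer + span > L - 200:
                    ok = False
                    break
                asm.append_free(spacer)
                chrom_genes.append(_assemble_gene(asm, plan, embed_records))
            if ok:
                break
        else:
            raise SimulationError(
                f"could not fit {per_chrom[ci]} genes into {chrom} "
                f"(length {L}); increase chrom_lengths or reduce n_genes")
        asm.append_free(L - asm.cursor)
        seq = asm.sequence()
        assert len(seq) == L
        genome[chrom] = seq
        genes.extend(chrom_genes)
        for kind, s, e, label in embed_records:
            if kind == "homopolymer":
                homopolymers.append(GenomicInterval(chrom, s, e, ".", label))
            else:
                repeats.append(GenomicInterval(chrom, s, e, ".", label))
        gene_no += per_chrom[ci]

    if config.include_chrM:
        chrom = "chrM"
        L = config.chrM_length
        asm = _ChromAssembler(chrom, np.random.default_rng([config.seed, 1, 99]))
        for _ in range(50):
            plan = _plan_gene(asm.rng, "geneM01", "+", "protein_coding",
                              b1_seq, b2_seq)
            # strip embeds: the chrM artifact class must fail only the chrM filter
            plan.intron_specs = [(length, None) for length, _ in plan.intron_specs]
            span = sum(len(s) for s in plan.mrna_exons) + \
                sum(length for length, _ in plan.intron_specs)
            if span + 200 <= L:
                break
        else:
            raise SimulationError("chrM too short for its gene")
        asm.append_free(80)
        genes.append(_assemble_gene(asm, plan, []))
        asm.append_free(L - asm.cursor)
        genome[chrom] = asm.sequence()

    return GenomeBuild(config, genome, genes, repeats, homopolymers)


def simulate_genome(config: SimConfig) -> tuple[dict[str, str],
                                                list[GenomicInterval],
                                                list[GenomicInterval]]:
    """Genome, repeat track and homopolymer track for a configuration."""
    b = GenomeBuild.from_config(config)
    return b.genome, b.repeats, b.homopolymers


def simulate_gene_models(config: SimConfig) -> list[Gene]:
    return GenomeBuild.from_config(config).genes


# ---------------------------------------------------------------------------
# site planting

def _min_dist(pos: int, arr: np.ndarray) -> int:
    if arr.size == 0:
        return 10 ** 9
    return int(np.min(np.abs(arr - pos)))


class _Occupancy:
    def __init__(self, sep: int):
        self.sep = sep
        self.taken: dict[str, set[int]] = {}

    def free(self, chrom: str, pos: int) -> bool:
        t = self.taken.setdefault(chrom, set())
        return all(p not in t for p in range(pos - self.sep + 1, pos + self.sep))

    def take(self, chrom: str, pos: int) -> None:
        self.taken.setdefault(chrom, set()).add(pos)


def _coding_A(build: GenomeBuild, chrom: str, pos: int, strand: str) -> bool:
    base = build.genome[chrom][pos]
    return base == ("A" if strand == "+" else "T")


def plant_sites(build: GenomeBuild, config: SimConfig | None = None,
                ) -> TruthTable:
    """Choose genomic positions and editing levels for all truth classes.

    Editing sites land on coding-strand adenosines (genomic A in + genes,
    genomic T in - genes); each artifact class is placed so that it violates
    exactly the filter named by its class.
    """
    config = config or build.config
    rng = np.random.default_rng([config.seed, 2])
    occ = _Occupancy(config.min_site_separation)

    # --- position pools -------------------------------------------------
    pools: dict[str, list[tuple[str, int, str, str, str]]] = {
        k: [] for k in ("intron", "intron_repeat", "utr3", "utr5", "cds",
                        "nc_exon", "nc_intron", "chrM", "splice",
                        "homopolymer", "simple")}
    rep_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in build.repeats:
        rep_by_chrom.setdefault(iv.chrom, []).append(iv)
    hp_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in build.homopolymers:
        hp_by_chrom.setdefault(iv.chrom, []).append(iv)

    def embed_at(chrom, pos):
        for iv in rep_by_chrom.get(chrom, []):
            if iv.contains(pos):
                return iv.name
        for iv in hp_by_chrom.get(chrom, []):
            if iv.contains(pos):
                return "homopolymer"
        return None

    for g in build.genes:
        t = g.transcripts[0]
        junctions = np.array(t.junctions(), dtype=int)
        is_m = g.chrom == "chrM"

        def eligible(pos, min_junc_dist=9):
            return (_coding_A(build, g.chrom, pos, g.strand)
                    and _min_dist(pos, junctions) >= min_junc_dist)

        # introns
        for (s1, e1), (s2, _) in zip(t.exons, t.exons[1:]):
            for pos in range(e1, s2):
                if not _coding_A(build, g.chrom, pos, g.strand):
                    continue
                emb = embed_at(g.chrom, pos)
                d = _min_dist(pos, junctions)
                rec = (g.chrom, pos, g.strand, g.gene_id, "intron")
                if emb == "homopolymer" and d >= 9 and not is_m:
                    pools["homopolymer"].append(rec)
                elif emb == "simple_repeat" and d >= 9 and not is_m:
                    pools["simple"].append(rec)
                elif emb in ("B1", "B2") and d >= 9 and not is_m:
                    pools["intron_repeat"].append(rec)
                elif emb is None and 1 <= d <= 6 and not is_m:
                    pools["splice"].append(rec)
                elif emb is None and d >= 9:
                    if is_m:
                        pools["chrM"].append(rec)
                    elif t.biotype == "protein_coding":
                        pools["intron"].append(rec)
                    else:
                        pools["nc_intron"].append(rec)
        # exonic regions
        utr5, utr3 = t.utr_intervals()
        for name, ivals in (("utr5", utr5), ("utr3", utr3), ("cds", t.cds)):
            for s, e in ivals:
                for pos in range(s, e):
                    if eligible(pos) and embed_at(g.chrom, pos) is None:
                        rec = (g.chrom, pos, g.strand, g.gene_id, name)
                        pools["chrM" if is_m else name].append(rec)
        if not t.is_coding:
            for s, e in t.exons:
                for pos in range(s, e):
                    if eligible(pos) and embed_at(g.chrom, pos) is None:
                        pools["nc_exon"].append(
                            (g.chrom, pos, g.strand, g.gene_id, "nc_exon"))

    # --- weighted sampling ----------------------------------------------
    def motif_weight(chrom, pos, strand):
        seq = build.genome[chrom]
        if strand == "+":
            nxt, prv = seq[pos + 1], seq[pos - 1]
        else:
            nxt = revcomp(seq[pos - 1])
            prv = revcomp(seq[pos + 1])
        w = 1.0
        if nxt == "G":
            w *= config.adar_motif_bias
        if prv != "G":
            w *= config.adar_motif_bias
        return w

    def draw(pool_name, n, biased=False):
        pool = pools[pool_name]
        picked = []
        if not pool:
            return picked
        w = np.array([motif_weight(c, p, s) if biased else 1.0
                      for c, p, s, _, _ in pool])
        alive = np.ones(len(pool), dtype=bool)
        while len(picked) < n and alive.any():
            ww = np.where(alive, w, 0.0)
            tot = ww.sum()
            if tot == 0:
                break
            i = int(rng.choice(len(pool), p=ww / tot))
            alive[i] = False
            c, p, s, gid, region = pool[i]
            if occ.free(c, p):
                occ.take(c, p)
                picked.append(pool[i])
        return picked

    def draw_mixed(n, biased=True):
        mix = (("intron", 0.42), ("intron_repeat", 0.18), ("utr3", 0.26),
               ("cds", 0.06), ("utr5", 0.02), ("nc_exon", 0.03),
               ("nc_intron", 0.03))
        counts = {k: int(round(n * frac)) for k, frac in mix}
        counts["intron"] += n - sum(counts.values())
        out = []
        for k, want in counts.items():
            got = draw(k, want, biased=biased)
            if len(got) < want:
                got += draw("intron", want - len(got), biased=biased)
            out.extend(got)
        return out

    records: list[TruthRecord] = []

    def add(recs, cls, lev_fn):
        for chrom, pos, strand, gid, region in recs:
            lc, lf = lev_fn()
            records.append(TruthRecord(chrom, pos, strand, cls, lc, lf,
                                       gid, region))

    null_sites = draw_mixed(config.n_null_edit_sites)
    if len(null_sites) < config.n_null_edit_sites:
        raise SimulationError(
            f"only {len(null_sites)} eligible coding-strand A positions for "
            f"{config.n_null_edit_sites} null editing sites; enlarge the genome")
    add(null_sites, "editing_null",
        lambda: (lambda l: (l, l))(rng.uniform(*config.null_level_range)))

    dre_sites = draw_mixed(config.n_dre_sites)
    if len(dre_sites) < config.n_dre_sites:
        raise SimulationError("insufficient eligible positions for DRE sites")

    def dre_levels():
        while True:
            lc = rng.uniform(*config.control_level_range)
            lf = rng.uniform(*config.fdm_level_range)
            if lc != lf:
                return lc, lf
    add(dre_sites, "editing_dre", dre_levels)

    n_het = config.n_snp_sites // 2
    snp_sites = draw_mixed(config.n_snp_sites, biased=False)
    if len(snp_sites) < config.n_snp_sites:
        raise SimulationError("insufficient eligible positions for SNPs")
    add(snp_sites[:n_het], "snp_het", lambda: (0.5, 0.5))
    add(snp_sites[n_het:], "snp_hom", lambda: (1.0, 1.0))

    n_per_art = config.n_artifact_sites // len(ARTIFACT_CLASSES)
    art_pools = {"artifact_splice": "splice", "artifact_homopolymer": "homopolymer",
                 "artifact_repeat": "simple", "artifact_chrM": "chrM",
                 "artifact_readend": "intron", "artifact_indel": "intron"}
    for cls, pool_name in art_pools.items():
        got = draw(pool_name, n_per_art, biased=False)
        if len(got) < n_per_art:
            raise SimulationError(
                f"only {len(got)} eligible positions in pool {pool_name!r} for "
                f"{cls} (need {n_per_art})")
        add(got, cls, lambda: (config.artifact_level, config.artifact_level))

    records.sort(key=lambda r: (r.chrom, r.pos))
    return TruthTable(records)


# ---------------------------------------------------------------------------
# read simulation

def _alt_base(strand: str) -> str:
    return "G" if strand == "+" else "C"


def simulate_alignments(build: GenomeBuild, truth: TruthTable,
                        config: SimConfig | None = None,
                        out_dir: str | Path = ".") -> dict[str, Path]:
    """Write one coordinate-sorted SAM per sample; returns sample -> path.

    At planted sites each overlapping read carries the alternative base with
    probability equal to the sample group's true level; read-end artifacts
    place alt bases only in the terminal 4% of reads, and indel artifacts put
    alt bases on reads carrying a 1-bp deletion adjacent to the site.
    """
    config = config or build.config
    if config.mean_depth <= 0:
        raise SimulationError("mean_depth must be > 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rl = config.read_length
    end_len = int(np.floor(0.04 * rl))
    chroms = list(build.genome)
    codes = {c: np.frombuffer(build.genome[c].encode(), dtype=np.uint8)
             for c in chroms}
    code_of = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        code_of[ord(b)] = i
    codes = {c: code_of[a] for c, a in codes.items()}

    truth_by_chrom: dict[str, list[TruthRecord]] = {}
    for r in truth.records:
        truth_by_chrom.setdefault(r.chrom, []).append(r)

    sheet = config.sample_sheet()
    paths: dict[str, Path] = {}
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{c}\tLN:{len(build.genome[c])}" for c in chroms]

    for si, sample in enumerate(config.sample_ids):
        rng = np.random.default_rng([config.seed, 1000 + si])
        group = sheet.groups[sample]
        is_fdm = group == config.group_labels[1]
        path = out_dir / f"{sample}.sam"
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for chrom in chroms:
                L = len(build.genome[chrom])
                n_reads = int(round(config.mean_depth * L / rl))
                starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))
                mat = codes[chrom][starts[:, None] + np.arange(rl)].copy()
                err = rng.random((n_reads, rl)) < config.base_error_rate
                shift = rng.integers(1, 4, size=(n_reads, rl), dtype=np.uint8)
                mat[err] = (mat[err] + shift[err]) % 4
                low = rng.random((n_reads, rl)) < config.low_qual_frac
                quals = np.where(low, config.base_qual_low,
                                 config.base_qual_high).astype(np.uint8)

                removed: set[int] = set()
                irregular: list[tuple[int, str, str, str]] = []
                for rec in truth_by_chrom.get(chrom, []):
                    level = rec.level_fdm if is_fdm else rec.level_control
                    alt = code_of[ord(_alt_base(rec.strand))]
                    lo = np.searchsorted(starts, rec.pos - rl + 1, "left")
                    hi = np.searchsorted(starts, rec.pos, "right")
                    cover = np.arange(lo, hi)
                    cover = cover[[i not in removed for i in cover]]
                    if config.mean_depth >= 20 and cover.size == 0:
                        raise SimulationError(
                            f"planted site {chrom}:{rec.pos + 1} uncovered in "
                            f"sample {sample}")
                    offs = rec.pos - starts[cover]
                    if rec.cls == "artifact_readend":
                        at_end = (offs < end_len) | (offs >= rl - end_len)
                        carry = at_end & (rng.random(cover.size) < 0.9)
                        mat[cover[carry], offs[carry]] = alt
                    elif rec.cls == "artifact_indel":
                        roomy = offs <= rl - 3
                        pick = roomy & (rng.random(cover.size) < 0.35)
                        for ri, off in zip(cover[pick], offs[pick]):
                            s = int(starts[ri])
                            if s + rl + 1 > L:
                                continue
                            removed.add(int(ri))
                            row = mat[ri].copy()
                            row[off] = alt
                            prefix = _BASE_BYTES[row[:off + 1]].tobytes().decode()
                            suffix = build.genome[chrom][rec.pos + 2:s + rl + 1]
                            q = np.where(
                                rng.random(rl) < config.low_qual_frac,
                                config.base_qual_low, config.base_qual_high)
                            cigar = f"{off + 1}M1D{rl - off - 1}M"
                            irregular.append(
                                (s, cigar, prefix + suffix,
                                 (q.astype(np.uint8) + 33).tobytes().decode()))
                    else:
                        carry = rng.random(cover.size) < level
                        mat[cover[carry], offs[carry]] = alt

                keep = np.ones(n_reads, dtype=bool)
                for i in removed:
                    keep[i] = False
                seq_bytes = _BASE_BYTES[mat]
                qual_bytes = (quals + 33)
                entries = []
                for i in np.nonzero(keep)[0]:
                    entries.append((int(starts[i]), f"{rl}M",
                                    seq_bytes[i].tobytes().decode(),
                                    qual_bytes[i].tobytes().decode()))
                entries.extend(irregular)
                entries.sort(key=lambda e: e[0])
                for k, (s, cigar, seq, qual) in enumerate(entries):
                    fh.write(f"{sample}.{chrom}.{k}\t0\t{chrom}\t{s + 1}\t60\t"
                             f"{cigar}\t*\t0\t0\t{seq}\t{qual}\n")
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# count-level simulation (no reads) for statistical calibration

def simulate_site_counts(n_sites: int, n_per_group: int = 6,
                         mean_depth: float = 50.0,
                         level_range: tuple[float, float] = (0.02, 0.30),
                         delta: float = 0.0,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site binomial allele counts for two groups at Poisson depth.

    Returns (alt, depth, is_group2) with alt/depth of shape
    (n_sites, 2*n_per_group).  Group-2 true levels are shifted by ``delta``
    (clipped to [0,1]); delta=0 gives a null simulation.
    """
    rng = rng or np.random.default_rng()
    n = 2 * n_per_group
    levels = rng.uniform(*level_range, size=n_sites)
    group2 = np.zeros(n, dtype=bool)
    group2[n_per_group:] = True
    p = np.tile(levels[:, None], (1, n))
    p[:, group2] = np.clip(p[:, group2] + delta, 0.0, 1.0)
    depth = rng.poisson(mean_depth, size=(n_sites, n)).clip(min=1)
    alt = rng.binomial(depth, p)
    return alt, depth, group2


# ---------------------------------------------------------------------------
# one-call dataset emission

def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the complete input set for a pipeline run.

    Emits genome.fa, genes.gff3, repeats.bed, homopolymers.bed,
    known_snps.vcf, known_editing.bed, samples.tsv, truth.tsv and one SAM per
    sample; returns a name -> path mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    build = GenomeBuild.from_config(config)
    truth = plant_sites(build, config)
    rng = np.random.default_rng([config.seed, 3])

    paths: dict[str, Path] = {}
    paths["genome"] = out_dir / "genome.fa"
    write_fasta(build.genome, paths["genome"])
    paths["gff"] = out_dir / "genes.gff3"
    write_gff3(build.genes, paths["gff"])
    paths["repeats"] = out_dir / "repeats.bed"
    write_bed(build.repeats, paths["repeats"])
    paths["homopolymers"] = out_dir / "homopolymers.bed"
    write_bed(build.homopolymers, paths["homopolymers"])

    snp_records = [(r.chrom, r.pos, build.genome[r.chrom][r.pos],
                    _alt_base(r.strand))
                   for r in truth.records if r.cls.startswith("snp")]
    paths["dbsnp"] = out_dir / "known_snps.vcf"
    write_vcf_sites(snp_records, build.chrom_lengths, paths["dbsnp"])

    edit_recs = truth.editing_records
    n_known = int(round(config.known_edit_frac * len(edit_recs)))
    known_idx = rng.choice(len(edit_recs), size=n_known, replace=False) \
        if n_known else np.array([], dtype=int)
    known = [GenomicInterval(edit_recs[i].chrom, edit_recs[i].pos,
                             edit_recs[i].pos + 1, edit_recs[i].strand,
                             "known_edit") for i in sorted(known_idx)]
    paths["known_editing"] = out_dir / "known_editing.bed"
    write_bed(known, paths["known_editing"])

    paths["samples"] = out_dir / "samples.tsv"
    config.sample_sheet().write_tsv(paths["samples"])
    paths["truth"] = out_dir / "truth.tsv"
    truth.write_tsv(paths["truth"])

    sam_paths = simulate_alignments(build, truth, config, out_dir)
    for sample, p in sam_paths.items():
        paths[f"sam:{sample}"] = p
    return paths


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["group_labels"] = list(d["group_labels"])
    d["chrom_lengths"] = list(d["chrom_lengths"])
    for k in ("null_level_range", "control_level_range", "fdm_level_range"):
        d[k] = list(d[k])
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for k in ("group_labels", "chrom_lengths", "null_level_range",
              "control_level_range", "fdm_level_range"):
        if k in d:
            d[k] = tuple(d[k])
    return SimConfig(**d)
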