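"""Coding-strand orientation and the editing-site removal cascade.

Candidates are A>G changes on the coding strand of a gene: genomic A>G inside
+ strand genes, genomic T>C inside - strand genes.  Candidates are then run
through the removal cascade in a fixed order:

    chrM -> homopolymer -> simple repeat -> splice proximity -> indel
    proximity -> read-end clustering -> known SNP (dbSNP-like) -> SNP-like
    AAF profile -> recurrence

Sites present in the known-editing track (REDIportal-like) bypass the whole
removal list, but every filter is still evaluated and logged for them.  Each
filter is a pure predicate of the site, so the accepted set is invariant to
filter order; only the logged first-failing filter depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genes import Gene
from .io import GenomicInterval
from .pileup import Observation, VariantCall

FILTER_ORDER = ("chrM", "homopolymer", "simple_repeat", "splice", "indel",
                "read_end", "dbsnp", "snp_profile", "recurrence")


@dataclass(frozen=True)
class FilterConfig:
    homopolymer_min_run: int = 5
    splice_max_dist: int = 6
    indel_max_dist: int = 1
    read_end_fraction: float = 0.04
    # "strict": remove iff every alt observation is within the terminal
    # fraction of its read.  "masked": remove iff, with the terminal fraction
    # of every read masked, no sample retains min_alt_depth alt observations
    # (i.e. the call would not survive end-trimming).  The masked rule is the
    # default because a single stray error read in the interior defeats the
    # strict rule.
    read_end_mode: str = "masked"
    snp_profile_sample_frac: float = 0.90
    snp_profile_het_band: tuple[float, float] = (0.40, 0.60)
    snp_profile_hom_value: float = 1.00
    min_edit_level: float = 0.01
    min_samples_at_level: int = 2
    min_depth_for_profile: int = 10
    exclude_chroms: frozenset = frozenset({"chrM", "MT", "chrMT"})
    simple_repeat_families: frozenset = frozenset({"simple_repeat"})

    def __post_init__(self):
        for f in (self.read_end_fraction, self.snp_profile_sample_frac,
                  self.min_edit_level):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0,1]")
        if self.homopolymer_min_run < 1:
            raise ValueError("homopolymer_min_run must be >= 1")


@dataclass
class EditingCandidate:
    """A coding-strand A>G candidate derived from a VariantCall."""

    call: VariantCall
    gene_ids: tuple[str, ...]
    strand: str
    known_site: bool = False

    @property
    def chrom(self) -> str:
        return self.call.chrom

    @property
    def pos(self) -> int:
        return self.call.pos

    @property
    def levels(self) -> np.ndarray:
        """Per-sample editing level: alt/(ref+alt) on oriented counts."""
        return self.call.aaf

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos + 1}"


@dataclass
class EditingSite:
    """An accepted high-confidence editing site."""

    chrom: str
    pos: int
    strand: str
    gene_ids: tuple[str, ...]
    ref: str
    alt: str
    samples: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    levels: np.ndarray
    known_site: bool

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos + 1}"


@dataclass
class Tracks:
    """External evidence tracks used by the cascade."""

    repeats: list[GenomicInterval] = field(default_factory=list)
    dbsnp: set = field(default_factory=set)          # (chrom,pos0,ref,alt)
    known_editing: set = field(default_factory=set)  # (chrom,pos0)

    def repeat_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for iv in self.repeats:
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv.name)
        return trees


# ---------------------------------------------------------------------------
# orientation

def orient_candidates(calls: list[VariantCall], genes: list[Gene],
                      known_editing: set | None = None
                      ) -> tuple[list[EditingCandidate], pd.DataFrame]:
    """Keep genomic A>G in + genes and genomic T>C in - genes.

    Positions inside genes on both strands are dropped as strand-ambiguous;
    everything else that is not a coding-strand A>G is dropped silently.
    Returns (candidates, log of ambiguous drops).
    """
    known_editing = known_editing or set()
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    candidates: list[EditingCandidate] = []
    ambiguous = []
    for call in calls:
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree.overlap(call.pos, call.pos + 1)]
        if not hits:
            continue
        strands = {g.strand for g in hits}
        if len(strands) > 1:
            ambiguous.append({"chrom": call.chrom, "pos": call.pos + 1,
                              "ref": call.ref, "alt": call.alt,
                              "reason": "genes_on_both_strands"})
            continue
        strand = strands.pop()
        wanted = ("A", "G") if strand == "+" else ("T", "C")
        if (call.ref, call.alt) != wanted:
            continue
        candidates.append(EditingCandidate(
            call, tuple(sorted(g.gene_id for g in hits)), strand,
            known_site=(call.chrom, call.pos) in known_editing))
    return candidates, pd.DataFrame(ambiguous)


# ---------------------------------------------------------------------------
# individual filter predicates (True = looks like an artifact / removed)

def in_homopolymer(genome: dict[str, str], chrom: str, pos: int,
                   min_run: int = 5) -> bool:
    """True iff pos lies in a maximal single-base run of length >= min_run."""
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} out of range for {chrom}")
    b = seq[pos]
    left = pos
    while left > 0 and seq[left - 1] == b:
        left -= 1
    right = pos
    while right + 1 < len(seq) and seq[right + 1] == b:
        right += 1
    return right - left + 1 >= min_run


def in_simple_repeat(trees: dict[str, IntervalTree], chrom: str, pos: int,
                     families: frozenset) -> bool:
    tree = trees.get(chrom)
    if tree is None:
        return False
    return any(iv.data in families for iv in tree.overlap(pos, pos + 1))


def near_splice(pos: int, junctions, max_dist: int = 6) -> bool:
    """True iff the site is within max_dist nt (inclusive) of an
    exon-boundary base of any splice junction."""
    arr = np.asarray(junctions, dtype=int)
    if arr.size == 0:
        return False
    return bool(np.min(np.abs(arr - pos)) <= max_dist)


def indel_adjacent(observations: dict[str, list[Observation]]) -> bool:
    """True iff any read in any sample has an I/D op within 1 nt of the site."""
    return any(ob.indel_adjacent for obs in observations.values() for ob in obs)


def _at_read_end(ob: Observation, fraction: float) -> bool:
    n = int(np.floor(fraction * ob.read_len))
    return ob.read_pos < n or ob.read_pos >= ob.read_len - n


def read_end_artifact(observations: dict[str, list[Observation]], alt: str,
                      fraction: float = 0.04, min_bq: int = 25,
                      mode: str = "strict", min_alt_depth: int = 2) -> bool:
    """Read-end clustering of the alt allele.

    mode="strict": True iff every quality-passing alt observation lies within
    floor(fraction * read_length) bases of either read end.  mode="masked":
    True iff after masking those terminal windows no sample retains
    ``min_alt_depth`` alt observations, i.e. the call would not have been
    made from read-interior evidence alone.
    """
    per_sample = {s: [ob for ob in obs if ob.base == alt and ob.qual >= min_bq]
                  for s, obs in observations.items()}
    if not any(per_sample.values()):
        raise ValueError("no alt-supporting observations at site")
    if mode == "strict":
        return all(_at_read_end(ob, fraction)
                   for obs in per_sample.values() for ob in obs)
    if mode == "masked":
        return not any(
            sum(1 for ob in obs if not _at_read_end(ob, fraction))
            >= min_alt_depth
            for obs in per_sample.values())
    raise ValueError(f"unknown read_end_mode {mode!r}")


def snp_like_profile(aafs, depths, config: FilterConfig) -> bool:
    """True iff >90% of qualifying samples have AAF == 100% or in 40-60%.

    Qualifying samples are those with depth >= min_depth_for_profile; with no
    qualifying samples the site is indistinguishable from a SNP and removed.
    """
    aafs = np.asarray(aafs, dtype=float)
    depths = np.asarray(depths)
    ok = depths >= config.min_depth_for_profile
    if not ok.any():
        return True
    lo, hi = config.snp_profile_het_band
    snpish = ((aafs[ok] == config.snp_profile_hom_value)
              | ((aafs[ok] >= lo) & (aafs[ok] <= hi)))
    return snpish.sum() / ok.sum() > config.snp_profile_sample_frac


def recurrent_enough(levels, min_level: float = 0.01,
                     min_samples: int = 2) -> bool:
    """True iff editing level >= min_level in at least min_samples samples."""
    levels = np.asarray(levels, dtype=float)
    return int((levels >= min_level).sum()) >= min_samples


# ---------------------------------------------------------------------------
# the cascade

def apply_filter_cascade(candidates: list[EditingCandidate],
                         genome: dict[str, str],
                         tracks: Tracks,
                         genes: list[Gene],
                         observations_for,
                         config: FilterConfig = FilterConfig(),
                         min_bq: int = 25,
                         ) -> tuple[list[EditingSite], pd.DataFrame]:
    """Run all removal filters over the candidates.

    ``observations_for(candidate) -> {sample: [Observation]}`` supplies the
    per-read evidence needed by the indel and read-end filters.  Returns the
    accepted sites and a per-candidate log with every filter's verdict, the
    first failing filter, and the final status (known sites bypass removal
    but keep their evaluations in the log).
    """
    if genome is None or tracks is None:
        raise ValueError("missing genome or tracks configuration")
    rep_trees = tracks.repeat_trees()
    junctions: dict[str, dict[str, np.ndarray]] = {}
    for g in genes:
        junctions.setdefault(g.gene_id, np.array(g.junctions(), dtype=int))

    accepted: list[EditingSite] = []
    log_rows = []
    for cand in candidates:
        obs = observations_for(cand)
        juncs = np.concatenate([junctions.get(gid, np.array([], dtype=int))
                                for gid in cand.gene_ids]) \
            if cand.gene_ids else np.array([], dtype=int)
        levels = cand.levels
        depths = cand.call.depths
        evals = {
            "chrM": cand.chrom in config.exclude_chroms,
            "homopolymer": in_homopolymer(genome, cand.chrom, cand.pos,
                                          config.homopolymer_min_run),
            "simple_repeat": in_simple_repeat(rep_trees, cand.chrom, cand.pos,
                                              config.simple_repeat_families),
            "splice": near_splice(cand.pos, juncs, config.splice_max_dist),
            "indel": indel_adjacent(obs),
            "read_end": read_end_artifact(obs, cand.call.alt,
                                          config.read_end_fraction, min_bq,
                                          mode=config.read_end_mode),
            "dbsnp": (cand.chrom, cand.pos, cand.call.ref,
                      cand.call.alt) in tracks.dbsnp,
            "snp_profile": snp_like_profile(levels, depths, config),
            "recurrence": not recurrent_enough(levels, config.min_edit_level,
                                               config.min_samples_at_level),
        }
        first_fail = next((name for name in FILTER_ORDER if evals[name]), "")
        status = "accepted" if (not first_fail or cand.known_site) else "removed"
        row = {"chrom": cand.chrom, "pos": cand.pos + 1, "strand": cand.strand,
               "gene": ",".join(cand.gene_ids), "known_site": cand.known_site}
        row.update({f"fail_{k}": evals[k] for k in FILTER_ORDER})
        row["first_fail"] = first_fail
        row["status"] = status
        row["exempt"] = bool(first_fail) and cand.known_site
        log_rows.append(row)
        if status == "accepted":
            accepted.append(EditingSite(
                cand.chrom, cand.pos, cand.strand, cand.gene_ids,
                cand.call.ref, cand.call.alt, cand.call.samples,
                cand.call.ref_counts, cand.call.alt_counts, levels,
                cand.known_site))
    return accepted, pd.DataFrame(log_rows)


def sites_to_frame(sites: list[EditingSite]) -> pd.DataFrame:
    """Accepted sites as a table (positions 1-based, per-sample level/count
    columns)."""
    rows = []
    for s in sites:
        row = {"chrom": s.chrom, "pos": s.pos + 1, "strand": s.strand,
               "gene": ",".join(s.gene_ids), "ref": s.ref, "alt": s.alt,
               "known_site": s.known_site}
        for i, sample in enumerate(s.samples):
            row[f"level:{sample}"] = float(s.levels[i])
            row[f"alt:{sample}"] = int(s.alt_counts[i])
            row[f"ref:{sample}"] = int(s.ref_counts[i])
        rows.append(row)
    return pd.DataFrame(rows)
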