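"""Per-sample pileups and multi-sample SNV calling.

Two routes exist and are tested for equivalence:

* ``build_pileup`` / ``call_snvs`` — a reference implementation that walks
  every read's CIGAR into per-base observations (base, quality, read-relative
  position, indel adjacency) and emits one ``PileupColumn`` per covered
  reference position.  Exact but slow; used on small inputs and as the
  contract definition.
* ``load_alignments`` / ``call_variants`` — the bulk path.  Pure-match reads
  of uniform length are kept in numpy arrays and counted with ``bincount``;
  reads with indels or soft clips are walked individually.  Detailed
  observations are then materialised only at called positions.

Depth at a position means quality-passing, non-N observations (deletions
contribute nothing; insertions attach to the preceding reference base as
indel-adjacency flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# pysam CIGAR op codes
_M_OPS = {0, 7, 8}      # M, =, X consume both
_I_OP, _D_OP, _N_OP, _S_OP, _H_OP, _P_OP = 1, 2, 3, 4, 5, 6


class PileupError(ValueError):
    pass


@dataclass(frozen=True)
class CallThresholds:
    """The calling thresholds: BQ>=25, depth>=10, alt depth>=2, AAF>=1%."""

    min_base_quality: int = 25
    min_depth: int = 10
    min_alt_depth: int = 2
    min_aaf: float = 0.01

    def __post_init__(self):
        if min(self.min_base_quality, self.min_depth, self.min_alt_depth) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.min_aaf <= 1:
            raise ValueError("min_aaf must be in (0, 1]")


@dataclass(frozen=True)
class Observation:
    """One read's base at one reference position."""

    base: str
    qual: int
    read_pos: int        # 0-based offset from the 5' end of the read
    read_len: int
    indel_adjacent: bool  # I/D CIGAR op within 1 nt on the same read


@dataclass
class PileupColumn:
    chrom: str
    pos: int                               # 0-based
    observations: dict[str, list[Observation]]  # sample -> observations


@dataclass
class VariantCall:
    """A multi-sample SNV with per-sample quality-filtered allele counts."""

    chrom: str
    pos: int            # 0-based
    ref: str
    alt: str
    samples: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    depths: np.ndarray  # all quality-passing non-N observations

    @property
    def aaf(self) -> np.ndarray:
        denom = self.ref_counts + self.alt_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, self.alt_counts / np.maximum(denom, 1), 0.0)
        return out

    @property
    def n_samples_called(self) -> int:
        return int(self._called_mask.sum()) if hasattr(self, "_called_mask") else 0


# ---------------------------------------------------------------------------
# CIGAR walking

def walk_cigar(pos: int, cigar: list[tuple[int, int]]
               ) -> tuple[list[tuple[int, int]], set[int]]:
    """Walk a CIGAR from reference position ``pos``.

    Returns (pairs, indel_adjacent) where pairs are (query_pos, ref_pos) for
    every aligned base and indel_adjacent is the set of reference positions
    within 1 nt of an insertion or deletion on this read.
    """
    pairs: list[tuple[int, int]] = []
    adjacent: set[int] = set()
    q, r = 0, pos
    for op, ln in cigar:
        if op in _M_OPS:
            pairs.extend((q + i, r + i) for i in range(ln))
            q += ln
            r += ln
        elif op == _I_OP:
            # insertion sits between r-1 and r
            adjacent.update((r - 1, r))
            q += ln
        elif op in (_D_OP, _N_OP):
            if op == _D_OP:
                adjacent.update(range(r - 1, r + ln + 1))
            r += ln
        elif op == _S_OP:
            q += ln
        elif op in (_H_OP, _P_OP):
            pass
        else:
            raise PileupError(f"unsupported CIGAR op {op}")
    return pairs, adjacent


# ---------------------------------------------------------------------------
# bulk alignment container

@dataclass
class _Irregular:
    pos: int
    cigar: list[tuple[int, int]]
    seq_codes: np.ndarray
    quals: np.ndarray
    read_len: int
    is_reverse: bool


@dataclass
class SampleAlignments:
    """Column-oriented storage of one sample's reads, keyed by chrom."""

    read_len: int
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    seqs: dict[str, np.ndarray] = field(default_factory=dict)    # (n, read_len)
    quals: dict[str, np.ndarray] = field(default_factory=dict)
    irregular: dict[str, list[_Irregular]] = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return sorted(set(self.starts) | set(self.irregular))


def load_alignments(path: str | Path,
                    genome: dict[str, str] | None = None) -> SampleAlignments:
    """Load a SAM file into a SampleAlignments store."""
    by_chrom: dict[str, list] = {}
    irregular: dict[str, list[_Irregular]] = {}
    lengths: dict[int, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for r in af:
            if r.is_unmapped or r.query_sequence is None:
                continue
            chrom = r.reference_name
            if genome is not None and chrom not in genome:
                raise PileupError(
                    f"{path}: read {r.query_name} maps to unknown chrom {chrom!r}")
            cig = list(r.cigartuples or ())
            seq = np.frombuffer(r.query_sequence.encode(), dtype=np.uint8)
            qual = np.array(r.query_qualities or [0] * len(seq), dtype=np.uint8)
            if len(cig) == 1 and cig[0][0] == 0:
                by_chrom.setdefault(chrom, []).append(
                    (r.reference_start, _CODE[seq], qual, r.is_reverse))
                lengths[len(seq)] = lengths.get(len(seq), 0) + 1
            else:
                irregular.setdefault(chrom, []).append(_Irregular(
                    r.reference_start, cig, _CODE[seq], qual, len(seq),
                    r.is_reverse))
    modal_len = max(lengths, key=lambda k: lengths[k]) if lengths else 0
    store = SampleAlignments(read_len=modal_len, irregular=irregular)
    for chrom, reads in by_chrom.items():
        uniform = [t for t in reads if len(t[1]) == modal_len and not t[3]]
        extra = [t for t in reads if len(t[1]) != modal_len or t[3]]
        for pos_, codes_, qual_, rev_ in extra:
            irregular.setdefault(chrom, []).append(_Irregular(
                pos_, [(0, len(codes_))], codes_, qual_, len(codes_), rev_))
        if uniform:
            order = np.argsort([t[0] for t in uniform], kind="stable")
            store.starts[chrom] = np.array([uniform[i][0] for i in order])
            store.seqs[chrom] = np.stack([uniform[i][1] for i in order])
            store.quals[chrom] = np.stack([uniform[i][2] for i in order])
    for chrom in irregular:
        irregular[chrom].sort(key=lambda ir: ir.pos)
    return store


# ---------------------------------------------------------------------------
# reference pileup

def build_pileup(stores: dict[str, SampleAlignments], genome: dict[str, str],
                 chroms: list[str] | None = None):
    """Yield a PileupColumn for every covered reference position (reference
    implementation; materialises observations for all reads)."""
    chroms = chroms or sorted({c for s in stores.values() for c in s.chroms()})
    for chrom in chroms:
        if chrom not in genome:
            raise PileupError(f"reads reference unknown chrom {chrom!r}")
        columns: dict[int, dict[str, list[Observation]]] = {}
        for sample, store in stores.items():
            for obs_pos, obs in _iter_sample_observations(store, chrom):
                columns.setdefault(obs_pos, {}).setdefault(sample, []).append(obs)
        for pos in sorted(columns):
            yield PileupColumn(chrom, pos, columns[pos])


def _iter_sample_observations(store: SampleAlignments, chrom: str):
    starts = store.starts.get(chrom)
    if starts is not None:
        seqs, quals = store.seqs[chrom], store.quals[chrom]
        rl = store.read_len
        for i in range(len(starts)):
            s = int(starts[i])
            for off in range(rl):
                base = BASES[seqs[i, off]] if seqs[i, off] < 4 else "N"
                yield s + off, Observation(base, int(quals[i, off]), off, rl, False)
    for ir in store.irregular.get(chrom, []):
        pairs, adj = walk_cigar(ir.pos, ir.cigar)
        for q, r in pairs:
            code = ir.seq_codes[q]
            base = BASES[code] if code < 4 else "N"
            rp = ir.read_len - 1 - q if ir.is_reverse else q
            yield r, Observation(base, int(ir.quals[q]), rp, ir.read_len,
                                 r in adj)


def observations_at(store: SampleAlignments, chrom: str, pos: int
                    ) -> list[Observation]:
    """All of one sample's observations at one reference position."""
    out: list[Observation] = []
    starts = store.starts.get(chrom)
    if starts is not None and len(starts):
        rl = store.read_len
        lo = np.searchsorted(starts, pos - rl + 1, "left")
        hi = np.searchsorted(starts, pos, "right")
        seqs, quals = store.seqs[chrom], store.quals[chrom]
        for i in range(int(lo), int(hi)):
            off = pos - int(starts[i])
            if 0 <= off < rl:
                code = seqs[i, off]
                base = BASES[code] if code < 4 else "N"
                out.append(Observation(base, int(quals[i, off]), off, rl, False))
    for ir in store.irregular.get(chrom, []):
        if ir.pos > pos:
            break
        pairs, adj = walk_cigar(ir.pos, ir.cigar)
        for q, r in pairs:
            if r == pos:
                code = ir.seq_codes[q]
                base = BASES[code] if code < 4 else "N"
                rp = ir.read_len - 1 - q if ir.is_reverse else q
                out.append(Observation(base, int(ir.quals[q]), rp,
                                       ir.read_len, r in adj))
    return out


# ---------------------------------------------------------------------------
# calling

def _passing(obs: Observation, min_bq: int) -> bool:
    return obs.base != "N" and obs.qual >= min_bq


def call_snvs(pileup, thresholds: CallThresholds, genome: dict[str, str],
              samples: list[str]) -> list[VariantCall]:
    """Call SNVs from a PileupColumn stream (reference implementation).

    A site is emitted when at least one sample passes all four thresholds for
    one alternative allele; counts are then reported for every sample.
    """
    if not samples:
        raise PileupError("no samples")
    out: list[VariantCall] = []
    for col in pileup:
        ref = genome[col.chrom][col.pos].upper()
        if ref not in BASES:
            continue
        counts = {s: np.zeros(4, dtype=int) for s in samples}
        for sample, obs_list in col.observations.items():
            for ob in obs_list:
                if _passing(ob, thresholds.min_base_quality):
                    counts[sample][BASES.index(ob.base)] += 1
        call = _evaluate_site(col.chrom, col.pos, ref, counts, samples,
                              thresholds)
        if call is not None:
            out.append(call)
    return out


def _evaluate_site(chrom, pos, ref, counts, samples, thresholds):
    ref_i = BASES.index(ref)
    totals = np.sum([counts[s] for s in samples], axis=0)
    alt_order = sorted((b for b in range(4) if b != ref_i),
                       key=lambda b: (-totals[b], BASES[b]))
    alt_i = alt_order[0]
    if totals[alt_i] == 0:
        return None
    depths = np.array([counts[s].sum() for s in samples])
    refs = np.array([counts[s][ref_i] for s in samples])
    alts = np.array([counts[s][alt_i] for s in samples])
    denom = refs + alts
    with np.errstate(divide="ignore", invalid="ignore"):
        aaf = np.where(denom > 0, alts / np.maximum(denom, 1), 0.0)
    passing = ((depths >= thresholds.min_depth)
               & (alts >= thresholds.min_alt_depth)
               & (aaf >= thresholds.min_aaf))
    if not passing.any():
        return None
    call = VariantCall(chrom, pos, ref, BASES[alt_i], list(samples),
                       refs, alts, depths)
    call._called_mask = passing
    return call


def call_variants(stores: dict[str, SampleAlignments], genome: dict[str, str],
                  thresholds: CallThresholds) -> list[VariantCall]:
    """Bulk SNV calling over all samples (bincount-based fast path)."""
    samples = list(stores)
    if not samples:
        raise PileupError("no samples")
    chroms = sorted({c for s in stores.values() for c in s.chroms()})
    out: list[VariantCall] = []
    for chrom in chroms:
        if chrom not in genome:
            raise PileupError(f"reads reference unknown chrom {chrom!r}")
        L = len(genome[chrom])
        per_sample = {}
        for sample in samples:
            per_sample[sample] = _count_matrix(stores[sample], chrom, L,
                                               thresholds.min_base_quality)
        total = sum(per_sample.values())
        ref_codes = _CODE[np.frombuffer(genome[chrom].encode(), dtype=np.uint8)]
        nonref = total.copy()
        valid = ref_codes < 4
        idx = np.arange(L)[valid]
        nonref[idx, ref_codes[valid]] = 0
        cand = np.nonzero(valid & (nonref.sum(axis=1)
                                   >= thresholds.min_alt_depth))[0]
        for pos in cand:
            ref = genome[chrom][pos]
            counts = {s: per_sample[s][pos] for s in samples}
            call = _evaluate_site(chrom, int(pos), ref, counts, samples,
                                  thresholds)
            if call is not None:
                out.append(call)
    return out


def _count_matrix(store: SampleAlignments, chrom: str, L: int,
                  min_bq: int) -> np.ndarray:
    counts = np.zeros((L, 4), dtype=np.int32)
    starts = store.starts.get(chrom)
    if starts is not None and len(starts):
        rl = store.read_len
        pos = (starts[:, None] + np.arange(rl)).ravel()
        codes = store.seqs[chrom].ravel()
        quals = store.quals[chrom].ravel()
        mask = (codes < 4) & (quals >= min_bq)
        flat = pos[mask] * 4 + codes[mask]
        counts += np.bincount(flat, minlength=L * 4).reshape(L, 4).astype(np.int32)
    for ir in store.irregular.get(chrom, []):
        pairs, _ = walk_cigar(ir.pos, ir.cigar)
        for q, r in pairs:
            if ir.seq_codes[q] < 4 and ir.quals[q] >= min_bq and 0 <= r < L:
                counts[r, ir.seq_codes[q]] += 1
    return counts
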