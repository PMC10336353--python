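"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with the most naive algorithm
available (run-length scans, exhaustive loops, grid maximisation,
hypergeometric enumeration) and shares no code with the package internals.
"""

from itertools import groupby

import numpy as np
from scipy.stats import hypergeom


# --- sequence ---------------------------------------------------------------

def rle_runs(seq: str) -> list[tuple[int, int, str]]:
    """(start, end, base) of every maximal single-base run, by run-length scan."""
    out = []
    pos = 0
    for base, grp in groupby(seq):
        n = len(list(grp))
        out.append((pos, pos + n, base))
        pos += n
    return out


def in_long_run(seq: str, pos: int, min_run: int) -> bool:
    for s, e, _ in rle_runs(seq):
        if s <= pos < e:
            return e - s >= min_run
    raise AssertionError


def translate(seq: str) -> str:
    table = {}
    bases = "TCAG"
    aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
           "VVVVAAAADDEEGGGG")
    i = 0
    for a in bases:
        for b in bases:
            for c in bases:
                table[a + b + c] = aas[i]
                i += 1
    return "".join(table[seq[k:k + 3]] for k in range(0, len(seq) - 2, 3))


# --- statistics -------------------------------------------------------------

def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed."""
    m = a + c
    n1, n2 = a + b, c + d
    N = n1 + n2
    lo, hi = max(0, m - n2), min(n1, m)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, N, m, n1)
    p_obs = hypergeom.pmf(a, N, m, n1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return np.clip(adj, 0, 1)


def grid_lrt(k1, n1, k2, n2, grid=200001):
    """LRT statistic via grid maximisation of the binomial likelihoods."""
    ps = np.linspace(1e-9, 1 - 1e-9, grid)

    def ll(k, n):
        return k * np.log(ps) + (n - k) * np.log1p(-ps)

    full = ll(k1, n1).max() + ll(k2, n2).max()
    null = (ll(k1, n1) + ll(k2, n2)).max()
    return 2 * (full - null)


# --- intervals --------------------------------------------------------------

def stab_depth(reads, pos):
    """Number of reads overlapping pos; reads are (start, ref_len)."""
    return sum(1 for s, ln in reads if s <= pos < s + ln)


def overlap_family(chrom, pos, intervals):
    """First (sorted) family label of intervals covering (chrom,pos)."""
    hits = sorted(name for c, s, e, name in intervals
                  if c == chrom and s <= pos < e)
    return hits[0] if hits else "none"


# --- filter cascade ---------------------------------------------------------

FILTERS = ("chrM", "homopolymer", "simple_repeat", "splice", "indel",
           "read_end", "dbsnp", "snp_profile", "recurrence")


def cascade_verdict(cand: dict, genome: dict, repeats, dbsnp: set,
                    junctions: dict, min_bq: int = 25) -> tuple[str, str]:
    """Independent evaluation of the nine removal rules.

    ``cand`` carries: chrom, pos, strand, ref, alt, gene_ids, known,
    levels (per sample), depths (per sample), obs {sample: [(base, qual,
    read_pos, read_len, indel_adj)]}.  Returns (status, first_fail).
    """
    chrom, pos = cand["chrom"], cand["pos"]
    fails = []
    if chrom in ("chrM", "MT", "chrMT"):
        fails.append("chrM")
    if in_long_run(genome[chrom], pos, 5):
        fails.append("homopolymer")
    simple = [iv for iv in repeats if iv[3] == "simple_repeat"]
    if overlap_family(chrom, pos, simple) != "none":
        fails.append("simple_repeat")
    juncs = [j for gid in cand["gene_ids"] for j in junctions.get(gid, [])]
    if juncs and min(abs(j - pos) for j in juncs) <= 6:
        fails.append("splice")
    all_obs = [ob for obs in cand["obs"].values() for ob in obs]
    if any(ob[4] for ob in all_obs):
        fails.append("indel")
    # masked read-end rule: interior alt support < 2 in every sample
    def interior_alt(obs):
        n = 0
        for base, qual, rp, rl, _ in obs:
            if base == cand["alt"] and qual >= min_bq:
                edge = int(np.floor(0.04 * rl))
                if not (rp < edge or rp >= rl - edge):
                    n += 1
        return n
    if all(interior_alt(obs) < 2 for obs in cand["obs"].values()):
        fails.append("read_end")
    if (chrom, pos, cand["ref"], cand["alt"]) in dbsnp:
        fails.append("dbsnp")
    aafs = [a for a, d in zip(cand["levels"], cand["depths"]) if d >= 10]
    if not aafs:
        fails.append("snp_profile")
    else:
        snpish = sum(1 for a in aafs if a == 1.0 or 0.40 <= a <= 0.60)
        if snpish / len(aafs) > 0.90:
            fails.append("snp_profile")
    if sum(1 for a in cand["levels"] if a >= 0.01) < 2:
        fails.append("recurrence")

    ordered = [f for f in FILTERS if f in fails]
    if not ordered or cand["known"]:
        return "accepted", ordered[0] if ordered else ""
    return "removed", ordered[0]
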