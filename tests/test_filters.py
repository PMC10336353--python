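import numpy as np
import pytest

from rnaedit.filters import (FILTER_ORDER, EditingCandidate, FilterConfig,
                             Tracks, apply_filter_cascade, in_homopolymer,
                             in_simple_repeat, near_splice, orient_candidates,
                             read_end_artifact, recurrent_enough,
                             snp_like_profile)
from rnaedit.genes import Gene, Transcript
from rnaedit.io import GenomicInterval
from rnaedit.pileup import Observation, VariantCall
import oracles


class TestHomopolymer:
    def test_run_of_five_detected_run_of_four_not(self):
        g = {"c": "GGCAAAAACCGTAAAATT"}
        assert in_homopolymer(g, "c", 6)          # middle of AAAAA
        assert not in_homopolymer(g, "c", 13)     # middle of AAAA
        with pytest.raises(ValueError):
            in_homopolymer(g, "c", 99)

    def test_agrees_with_rle_oracle_everywhere(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=10000))
        g = {"c": seq}
        long_runs = [(s, e) for s, e, _ in oracles.rle_runs(seq) if e - s >= 5]
        in_run = np.zeros(len(seq), dtype=bool)
        for s, e in long_runs:
            in_run[s:e] = True
        for pos in range(len(seq)):
            assert in_homopolymer(g, "c", pos) == bool(in_run[pos])


class TestSplice:
    def test_inclusive_distance_threshold(self):
        assert near_splice(106, [100])        # distance 6: removed
        assert not near_splice(107, [100])    # distance 7: kept
        assert not near_splice(107, [])       # single-exon gene


class TestReadEnd:
    @staticmethod
    def _obs(offsets, read_len=100, base="G", qual=30):
        return [Observation(base, qual, o, read_len, False) for o in offsets]

    def test_strict_all_alt_at_ends(self):
        obs = {"s1": self._obs([0, 1, 2, 3]) + self._obs([50], base="A")}
        assert read_end_artifact(obs, "G", mode="strict")
        obs2 = {"s1": self._obs([0, 1, 3, 50])}
        assert not read_end_artifact(obs2, "G", mode="strict")

    def test_strict_matches_exhaustive_oracle_on_mixed_offsets(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            offs = rng.integers(0, 100, size=rng.integers(1, 8))
            obs = {"s1": self._obs(offs.tolist())}
            expected = all(o < 4 or o >= 96 for o in offs)
            assert read_end_artifact(obs, "G", mode="strict") == expected

    def test_masked_requires_interior_support_in_some_sample(self):
        ends = self._obs([0, 1, 2, 97])
        assert read_end_artifact({"s1": ends + self._obs([50])}, "G",
                                 mode="masked")     # 1 interior alt < 2
        assert not read_end_artifact({"s1": ends + self._obs([50, 60])}, "G",
                                     mode="masked")  # call survives trimming

    def test_low_quality_alt_ignored(self):
        obs = {"s1": self._obs([0, 1]) + self._obs([50], qual=20)}
        assert read_end_artifact(obs, "G", mode="strict")

    def test_no_alt_observations_is_an_error(self):
        with pytest.raises(ValueError):
            read_end_artifact({"s1": self._obs([3], base="A")}, "G")


class TestSnpProfile:
    CFG = FilterConfig()

    def test_all_samples_at_half_removed(self):
        assert snp_like_profile([0.5] * 12, [50] * 12, self.CFG)

    def test_half_samples_at_half_kept(self):
        assert not snp_like_profile([0.5] * 6 + [0.05] * 6, [50] * 12, self.CFG)

    def test_eleven_of_twelve_hom_removed(self):
        # 11/12 = 91.7% > 90%
        assert snp_like_profile([1.0] * 11 + [0.05], [50] * 12, self.CFG)

    def test_low_depth_samples_do_not_qualify(self):
        aafs = [0.5] * 6 + [0.05] * 6
        depths = [50] * 6 + [5] * 6   # only the SNP-like samples qualify
        assert snp_like_profile(aafs, depths, self.CFG)

    def test_zero_qualifying_samples_removed(self):
        assert snp_like_profile([0.2] * 4, [3] * 4, self.CFG)


class TestRecurrence:
    def test_threshold_edges(self):
        assert not recurrent_enough([0.05] + [0.0] * 11)   # one sample only
        assert recurrent_enough([0.01, 0.01] + [0.0] * 10)
        assert not recurrent_enough([0.0] * 12)


# ---------------------------------------------------------------------------

def _gene(gene_id, chrom, strand, start, end, junctions=()):
    # a single-exon transcript unless junction coordinates are requested
    if junctions:
        j = sorted(junctions)[0]
        exons = [(start, j + 1), (sorted(junctions)[1], end)]
    else:
        exons = [(start, end)]
    t = Transcript(gene_id + ".t", chrom, strand, "protein_coding", exons)
    return Gene(gene_id, chrom, strand, "protein_coding", [t])


def _call(chrom, pos, ref, alt, alts=(5, 5), refs=(45, 45)):
    return VariantCall(chrom, pos, ref, alt, ["s1", "s2"],
                       np.array(refs), np.array(alts),
                       np.array(refs) + np.array(alts))


class TestOrientation:
    GENES = [_gene("gp", "chr1", "+", 100, 200),
             _gene("gm", "chr1", "-", 300, 400),
             _gene("ga", "chr1", "+", 500, 600),
             _gene("gb", "chr1", "-", 550, 650)]

    def test_minus_strand_TC_is_candidate(self):
        cands, _ = orient_candidates([_call("chr1", 350, "T", "C")], self.GENES)
        assert len(cands) == 1 and cands[0].strand == "-"

    def test_minus_strand_AG_is_not(self):
        cands, _ = orient_candidates([_call("chr1", 350, "A", "G")], self.GENES)
        assert cands == []

    def test_intergenic_AG_is_not(self):
        cands, _ = orient_candidates([_call("chr1", 250, "A", "G")], self.GENES)
        assert cands == []

    def test_overlapping_opposite_strand_genes_ambiguous(self):
        cands, log = orient_candidates([_call("chr1", 560, "A", "G")], self.GENES)
        assert cands == []
        assert len(log) == 1 and log.iloc[0]["reason"] == "genes_on_both_strands"

    def test_known_site_flag_carried(self):
        cands, _ = orient_candidates([_call("chr1", 150, "A", "G")], self.GENES,
                                     known_editing={("chr1", 150)})
        assert cands[0].known_site


class TestCascade:
    def _setup(self):
        seq = list("ACGT" * 250)
        seq[200:206] = "AAAAAA"
        genome = {"chr1": "".join(seq), "chrM": "ACGT" * 125}
        genes = [_gene("g1", "chr1", "+", 50, 900),
                 _gene("gM", "chrM", "+", 10, 490)]
        tracks = Tracks(repeats=[GenomicInterval("chr1", 600, 650, ".",
                                                 "simple_repeat")],
                        dbsnp=set(), known_editing=set())
        return genome, genes, tracks

    @staticmethod
    def _obs_provider(cand):
        return {"s1": [Observation("G", 30, 50, 100, False)] * 5
                + [Observation("A", 30, 40, 100, False)] * 45,
                "s2": [Observation("G", 30, 60, 100, False)] * 5
                + [Observation("A", 30, 40, 100, False)] * 45}

    def test_chrM_candidate_removed_with_reason(self):
        genome, genes, tracks = self._setup()
        cand = EditingCandidate(_call("chrM", 100, "A", "G"), ("gM",), "+")
        accepted, log = apply_filter_cascade([cand], genome, tracks, genes,
                                             self._obs_provider)
        assert accepted == []
        assert log.iloc[0]["first_fail"] == "chrM"

    def test_known_site_in_homopolymer_accepted_with_exemption_logged(self):
        genome, genes, tracks = self._setup()
        cand = EditingCandidate(_call("chr1", 202, "A", "G"), ("g1",), "+",
                                known_site=True)
        accepted, log = apply_filter_cascade([cand], genome, tracks, genes,
                                             self._obs_provider)
        assert len(accepted) == 1 and accepted[0].known_site
        row = log.iloc[0]
        assert row["fail_homopolymer"] and row["exempt"] \
            and row["status"] == "accepted"

    def test_accepted_sites_are_coding_strand_AG(self):
        genome, genes, tracks = self._setup()
        cand = EditingCandidate(_call("chr1", 400, "A", "G"), ("g1",), "+")
        accepted, _ = apply_filter_cascade([cand], genome, tracks, genes,
                                           self._obs_provider)
        (site,) = accepted
        assert (site.ref, site.alt, site.strand) == ("A", "G", "+")

    def test_missing_tracks_is_configuration_error(self):
        genome, genes, _ = self._setup()
        with pytest.raises(ValueError, match="tracks"):
            apply_filter_cascade([], genome, None, genes, self._obs_provider)


# ---------------------------------------------------------------------------
# randomised equivalence against the independent oracle

def random_cascade_inputs(n=1000, seed=17):
    """Build a toy genome/tracks and n random candidates with observations."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=20000))
    for s in range(500, 20000, 1500):       # sprinkle homopolymer runs
        b = "ACGT"[rng.integers(0, 4)]
        for k in range(int(rng.integers(5, 9))):
            seq[s + k] = b
    genome = {"chr1": "".join(seq), "chrM": "".join(
        rng.choice(list("ACGT"), size=2000))}
    genes = [_gene("g1", "chr1", "+", 0, 10000, junctions=(4000, 4200)),
             _gene("g2", "chr1", "+", 10000, 20000),
             _gene("gM", "chrM", "+", 0, 2000)]
    repeats = [GenomicInterval("chr1", int(s), int(s) + 80, ".",
                               "simple_repeat" if i % 2 else "B1")
               for i, s in enumerate(range(1000, 19000, 2600))]
    dbsnp = {("chr1", int(p), "A", "G")
             for p in rng.integers(0, 20000, size=300)}
    samples = [f"s{i}" for i in range(6)]

    candidates, oracle_cands = [], []
    for i in range(n):
        if rng.random() < 0.05:
            chrom, gene_ids = "chrM", ("gM",)
            pos = int(rng.integers(10, 1990))
        else:
            chrom = "chr1"
            pos = int(rng.integers(10, 19990))
            gene_ids = ("g1",) if pos < 10000 else ("g2",)
        depths = rng.integers(0, 60, size=6)
        alts = np.minimum(rng.integers(0, 30, size=6), depths)
        # occasionally force SNP-like AAF patterns
        u = rng.random()
        if u < 0.15:
            alts = (depths * 0.5).astype(int)
        elif u < 0.25:
            alts = depths.copy()
        refs = depths - alts
        call = VariantCall(chrom, pos, "A", "G", samples, refs, alts,
                           depths.copy())
        known = rng.random() < 0.1
        obs = {}
        for s in samples:
            lst = []
            n_alt = max(int(rng.integers(1, 6)), 1)
            for _ in range(n_alt):
                rl = 100
                rp = int(rng.choice([0, 1, 2, 50, 97, 98, 99]))
                lst.append(Observation("G", int(rng.choice([20, 30])), rp, rl,
                                       bool(rng.random() < 0.05)))
            for _ in range(int(rng.integers(0, 10))):
                lst.append(Observation("A", 30, int(rng.integers(0, 100)),
                                       100, bool(rng.random() < 0.02)))
            obs[s] = lst
        candidates.append((EditingCandidate(call, gene_ids, "+", known), obs))
        with np.errstate(invalid="ignore"):
            levels = np.where(depths > 0, alts / np.maximum(depths, 1), 0.0)
        oracle_cands.append({
            "chrom": chrom, "pos": pos, "strand": "+", "ref": "A", "alt": "G",
            "gene_ids": gene_ids, "known": known,
            "levels": levels.tolist(), "depths": depths.tolist(),
            "obs": {s: [(o.base, o.qual, o.read_pos, o.read_len,
                         o.indel_adjacent) for o in obs[s]] for s in samples},
        })
    return genome, genes, repeats, dbsnp, candidates, oracle_cands


class TestCascadeOracleEquivalence:
    def test_thousand_random_candidates_match_brute_force(self):
        genome, genes, repeats, dbsnp, candidates, oracle_cands = \
            random_cascade_inputs()
        tracks = Tracks(repeats=repeats, dbsnp=dbsnp, known_editing=set())
        obs_map = {id(c): o for (c, o) in candidates}
        accepted, log = apply_filter_cascade(
            [c for c, _ in candidates], genome, tracks, genes,
            lambda cand: obs_map[id(cand)])
        junctions = {g.gene_id: g.junctions() for g in genes}
        rep = [(iv.chrom, iv.start, iv.end, iv.name) for iv in repeats]
        for (cand, _), oc, (_, row) in zip(candidates, oracle_cands,
                                           log.iterrows()):
            status, first = oracles.cascade_verdict(oc, genome, rep, dbsnp,
                                                    junctions)
            assert row["status"] == status, oc
            assert row["first_fail"] == first, oc

    def test_accepted_set_invariant_to_filter_order(self):
        """Each filter is a pure predicate, so the accepted set must not
        depend on evaluation order; check via the per-filter log columns."""
        genome, genes, repeats, dbsnp, candidates, _ = \
            random_cascade_inputs(n=300, seed=23)
        tracks = Tracks(repeats=repeats, dbsnp=dbsnp, known_editing=set())
        obs_map = {id(c): o for (c, o) in candidates}
        _, log = apply_filter_cascade(
            [c for c, _ in candidates], genome, tracks, genes,
            lambda cand: obs_map[id(cand)])
        any_fail = log[[f"fail_{f}" for f in FILTER_ORDER]].any(axis=1)
        removed = (log["status"] == "removed") & ~log["known_site"]
        assert (removed == (any_fail & ~log["known_site"])).all()
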