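import filecmp
from pathlib import Path

import numpy as np
import pytest

from rnaedit.genes import revcomp
from rnaedit.pileup import CallThresholds, call_variants, load_alignments
from rnaedit.simulate import (GenomeBuild, SimConfig, SimulationError,
                              plant_sites, simulate_alignments,
                              simulate_dataset, simulate_site_counts)
from conftest import SMALL_CONFIG
import oracles


class TestGenomeBuild:
    def test_same_seed_gives_identical_genome(self, small_config, small_build):
        again = GenomeBuild.from_config(SimConfig(**SMALL_CONFIG))
        assert again.genome == small_build.genome

    def test_chrom_length_mismatch_rejected(self):
        with pytest.raises(SimulationError, match="chrom_lengths"):
            SimConfig(n_chroms=2, chrom_lengths=(30000,))

    def test_chrM_present_iff_configured(self, small_build):
        assert "chrM" in small_build.genome
        cfg = dict(SMALL_CONFIG, include_chrM=False, n_artifact_sites=0)
        b = GenomeBuild.from_config(SimConfig(**cfg))
        assert "chrM" not in b.genome

    def test_recorded_homopolymers_match_run_length_scan(self, small_build):
        """Brute-force RLE scan of the emitted sequence reproduces the
        recorded homopolymer track exactly."""
        for chrom, seq in small_build.genome.items():
            found = {(s, e) for s, e, b in oracles.rle_runs(seq) if e - s >= 5}
            recorded = {(iv.start, iv.end) for iv in small_build.homopolymers
                        if iv.chrom == chrom}
            assert found == recorded

    def test_repeat_track_intervals_contain_their_unit(self, small_build):
        for iv in small_build.repeats:
            assert len(iv) >= 20
            if iv.name == "simple_repeat":
                s = small_build.genome[iv.chrom][iv.start:iv.end]
                assert set(s) <= {"C", "A"} or set(s) <= {"T", "G"}


class TestGeneModels:
    def test_cds_lengths_divisible_by_three_with_terminal_stop(self, small_build):
        for g in small_build.genes:
            t = g.transcripts[0]
            if not t.is_coding:
                continue
            cds = t.cds_sequence(small_build.genome)
            assert len(cds) % 3 == 0
            aa = oracles.translate(cds)
            assert aa.endswith("*")
            assert "*" not in aa[:-1], f"internal stop in {g.gene_id}"

    def test_both_strands_present(self, small_build):
        strands = {g.strand for g in small_build.genes}
        assert strands == {"+", "-"}

    def test_junction_count_matches_exon_count(self, small_build):
        for g in small_build.genes:
            t = g.transcripts[0]
            assert len(t.junctions()) == 2 * (len(t.exons) - 1)


class TestPlanting:
    def test_minus_strand_editing_sites_sit_on_genomic_T(self, small_build,
                                                         small_truth):
        minus = [r for r in small_truth.editing_records if r.strand == "-"]
        assert minus, "expected some planted sites on - strand genes"
        for r in minus:
            assert small_build.genome[r.chrom][r.pos] == "T"
        for r in small_truth.editing_records:
            if r.strand == "+":
                assert small_build.genome[r.chrom][r.pos] == "A"

    def test_class_placement_verified_by_interval_oracle(self, small_build,
                                                         small_truth):
        """Re-check every planted site against genome and annotation with
        independent interval queries."""
        junctions = {g.gene_id: g.junctions() for g in small_build.genes}
        rep = [(iv.chrom, iv.start, iv.end, iv.name)
               for iv in small_build.repeats]
        for r in small_truth.records:
            seq = small_build.genome[r.chrom]
            if r.cls == "artifact_splice":
                assert min(abs(j - r.pos) for j in junctions[r.gene_id]) <= 6
            elif r.cls == "artifact_homopolymer":
                assert oracles.in_long_run(seq, r.pos, 5)
            elif r.cls == "artifact_repeat":
                fam = oracles.overlap_family(r.chrom, r.pos, rep)
                assert fam == "simple_repeat"
            elif r.cls == "artifact_chrM":
                assert r.chrom == "chrM"
            else:
                # clean classes must violate none of the positional filters
                assert not oracles.in_long_run(seq, r.pos, 5)
                assert min(abs(j - r.pos) for j in junctions[r.gene_id]) > 6
                assert oracles.overlap_family(
                    r.chrom, r.pos,
                    [t for t in rep if t[3] == "simple_repeat"]) == "none"

    def test_dre_records_have_unequal_group_levels(self, small_truth):
        for r in small_truth.by_class("editing_dre"):
            assert r.level_control != r.level_fdm

    def test_motif_bias_enriches_G_downstream(self, small_build, small_truth):
        """With adar_motif_bias > 1, planted sites show more G at +1 than at
        -1 on the coding strand."""
        plus1 = minus1 = 0
        for r in small_truth.editing_records:
            seq = small_build.genome[r.chrom]
            if r.strand == "+":
                nxt, prv = seq[r.pos + 1], seq[r.pos - 1]
            else:
                nxt, prv = revcomp(seq[r.pos - 1]), revcomp(seq[r.pos + 1])
            plus1 += nxt == "G"
            minus1 += prv == "G"
        assert plus1 > minus1


@pytest.fixture(scope="module")
def sams(small_build, small_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("sams")
    return simulate_alignments(small_build, small_truth, out_dir=out)


class TestAlignments:
    def test_same_seed_gives_identical_sam_bytes(self, small_build, small_truth,
                                                 sams, tmp_path):
        paths2 = simulate_alignments(small_build, small_truth, out_dir=tmp_path)
        sample = sorted(sams)[0]
        assert filecmp.cmp(sams[sample], paths2[sample], shallow=False)

    def test_het_snp_aaf_near_half_and_dre_levels_recovered(
            self, small_build, small_truth, sams):
        stores = {s: load_alignments(p, small_build.genome)
                  for s, p in sams.items()}
        calls = {(c.chrom, c.pos): c
                 for c in call_variants(stores, small_build.genome,
                                        CallThresholds())}
        het_means = []
        for r in small_truth.by_class("snp_het"):
            c = calls.get((r.chrom, r.pos))
            assert c is not None
            het_means.append(np.mean(c.aaf))
        assert abs(np.mean(het_means) - 0.5) < 0.05

        cfg = small_build.config
        n = cfg.n_per_group
        for r in small_truth.by_class("editing_dre"):
            c = calls.get((r.chrom, r.pos))
            if c is None:
                continue
            ctrl = np.mean(c.aaf[:n])
            depth = np.mean(c.depths[:n]) * n
            se = np.sqrt(r.level_control * (1 - r.level_control) / depth)
            assert abs(ctrl - r.level_control) < 4 * se + 0.01

    def test_readend_artifacts_only_at_read_ends(self, small_build,
                                                 small_truth, sams):
        from rnaedit.pileup import observations_at
        store = load_alignments(sorted(sams.values())[0], small_build.genome)
        rl = small_build.config.read_length
        edge = int(0.04 * rl)
        for r in small_truth.by_class("artifact_readend"):
            for ob in observations_at(store, r.chrom, r.pos):
                if ob.base == ("G" if r.strand == "+" else "C") and ob.qual >= 25:
                    assert ob.read_pos < edge or ob.read_pos >= rl - edge

    def test_zero_depth_rejected(self, small_build, small_truth, tmp_path):
        bad = SimConfig(**dict(SMALL_CONFIG, mean_depth=0.0))
        with pytest.raises(SimulationError, match="mean_depth"):
            simulate_alignments(small_build, small_truth, config=bad,
                                out_dir=tmp_path)


class TestDatasetEmission:
    def test_dataset_files_written_and_deterministic(self, tmp_path):
        cfg = SimConfig(**dict(SMALL_CONFIG, seed=12))
        a = simulate_dataset(cfg, tmp_path / "a")
        b = simulate_dataset(cfg, tmp_path / "b")
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key
        for key in ("genome", "gff", "repeats", "dbsnp", "known_editing",
                    "samples", "truth"):
            assert Path(a[key]).exists()


class TestSiteCounts:
    def test_counts_match_requested_shift(self):
        rng = np.random.default_rng(5)
        alt, depth, g2 = simulate_site_counts(
            3000, mean_depth=80, level_range=(0.10, 0.10), delta=0.15, rng=rng)
        lv = alt / depth
        assert abs(lv[:, ~g2].mean() - 0.10) < 0.01
        assert abs(lv[:, g2].mean() - 0.25) < 0.01
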