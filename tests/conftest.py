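import numpy as np
import pytest

from rnaedit.genes import Gene, Transcript
from rnaedit.pipeline import run_all
from rnaedit.simulate import GenomeBuild, SimConfig, plant_sites

# Reduced design used where full-scale defaults are unnecessary: one
# chromosome, 7 genes, one artifact of each class, 30x depth.
SMALL_CONFIG = dict(seed=11, n_chroms=1, chrom_lengths=(16000,), n_genes=7,
                    mean_depth=30.0, n_null_edit_sites=40, n_dre_sites=8,
                    n_snp_sites=10, n_artifact_sites=6)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_build(small_config):
    return GenomeBuild.from_config(small_config)


@pytest.fixture(scope="session")
def small_truth(small_build, small_config):
    return plant_sites(small_build, small_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the study-design defaults (6 vs 6, depth 50,
    500 null + 50 DRE + 50 SNP + 60 artifact sites), shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    config = SimConfig(seed=1)
    manifest = run_all(out, sim_config=config)
    return {"config": config, "out": out, "manifest": manifest}


def write_sam(path, chrom_lengths, reads):
    """reads: (name, chrom, pos0, cigar, seq, quals[list of ints])."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for name, chrom, pos0, cigar, seq, quals in reads:
            q = "".join(chr(x + 33) for x in quals)
            fh.write(f"{name}\t0\t{chrom}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t"
                     f"{seq}\t{q}\n")


def make_coding_gene(codons, chrom="chrT", strand="+", gene_id="geneT",
                     utr5=9, utr3=9, flank=20, biotype="protein_coding"):
    """Single-exon coding gene whose CDS is the given codon list.

    Returns (genome, gene).  For '-' strand the genomic sequence is the
    reverse complement placed at the same locus.
    """
    from rnaedit.genes import revcomp
    cds = "".join(codons)
    mrna = "C" * utr5 + cds + "C" * utr3
    locus = mrna if strand == "+" else revcomp(mrna)
    seq = "T" * flank + locus + "T" * flank
    start = flank
    end = flank + len(mrna)
    if strand == "+":
        cds_iv = (start + utr5, start + utr5 + len(cds))
    else:
        cds_iv = (start + utr3, start + utr3 + len(cds))
    tx = Transcript(gene_id + ".t1", chrom, strand, biotype,
                    [(start, end)], [cds_iv])
    gene = Gene(gene_id, chrom, strand, biotype, [tx])
    return {chrom: seq}, gene
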