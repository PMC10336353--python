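# Methods

## Scope and model of the data

`rnaedit` starts from aligned reads (SAM), a reference genome and gene
models, i.e. downstream of trimming, alignment, duplicate removal and base
quality recalibration. At a genomic position in one sample the data are the
quality-passing read observations; at an editing site the alternative-allele
count is modelled as Binomial(n, π) with n the allele depth and π the
editing level of that sample's group. "Editing level" and "AAF" are the same
quantity, alt/(alt+ref), computed on quality-passing observations on the
coding strand.

## Calling

Depth at a position means quality-passing (Q ≥ 25), non-N observations after
masking; deletions contribute no observation and insertions attach to the
preceding reference base as indel-adjacency flags. A site is emitted when at
least one sample simultaneously satisfies depth ≥ 10, alt depth ≥ 2 and
AAF ≥ 1% for one alternative allele; counts are then reported for every
sample so that downstream editing levels have consistent denominators.
Multi-allelic columns collapse to the highest-count alternative allele, ties
broken lexicographically for determinism. Two code paths exist — a
per-observation reference implementation and a vectorised bincount path for
whole datasets — and the test suite asserts their equivalence on fixtures
that include indel-containing reads.

## The removal cascade

Each filter is a pure predicate of the candidate, so the accepted set is
independent of evaluation order; the order (chrM → homopolymer → simple
repeat → splice → indel → read-end → known SNP → SNP profile → recurrence)
only determines which filter is logged as the first failure. Distances to
splice junctions are measured to the exon-boundary base, inclusive
(distance 6 removes, 7 keeps). Known-editing sites bypass the entire removal
list but their per-filter verdicts are still logged, preserving
auditability. The SNP-profile filter evaluates AAFs only over samples with
depth ≥ 10 (AAF is undefined at low depth); with no qualifying sample the
site cannot be distinguished from a SNP and is removed. Known-SNP matching
is by exact (chrom, pos, ref, alt) so that true editing adjacent to a
catalogued SNP allele is not discarded.

Two rules had genuinely open readings:

* **Read-end filter.** A strict rule ("remove iff *every* alt observation
  lies in the terminal 4% of its read") is defeated by a single
  sequencing-error alt read in a read interior, which at realistic error
  rates happens for a third of genuine read-end artifacts. The default is
  therefore a masking rule: terminal windows of floor(0.04 × read length)
  bases are masked and the site is removed iff no sample retains ≥ 2 alt
  observations — i.e. the call would not have been made from read-interior
  evidence. The strict variant remains available
  (`FilterConfig(read_end_mode="strict")`).
* **Fisher FDR family.** The Fisher test is only run for sites passing the
  GLM p < 0.05 gate. Adjusting the gated p-values as if they were the whole
  family ignores that selection; when the gated set is signal-rich this
  assigns FDR < 0.2 to null sites with p ≈ 0.1 and the realised
  false-discovery proportion of the DRE set rises well above the nominal
  0.2. The default therefore keeps the family at all tested sites, entering
  ungated sites at p = 1 (a conservative, valid BH family); the
  literal per-set adjustment is available
  (`TestConfig(selection_adjusted_fisher=False)`).

## Differential testing

The GLM is binomial with logit link and a single group factor. Its MLE is
available in closed form (pooled per-group proportions), so the LRT
statistic 2(ll_full − ll_null) is computed analytically and compared to
χ²(1); statsmodels' iterative GLM fit is used in the tests as an independent
oracle, never as the implementation. Separation (a group at 0% or 100%) is
handled by the boundary likelihood with 0·log 0 = 0. Two optional modes
exist: a group-label permutation p-value (for readers of "empirical p" as
permutation-based) and a quasi-binomial dispersion rescaling; both are off
by default because the simulated counts are exactly binomial and the
asymptotic p is calibrated there (type-I rate ≈ 0.04–0.06 at the default
design; asserted in the acceptance suite). Direction of a DRE site is the
sign of the difference of unweighted per-sample mean levels — pooled counts
would let one deep sample dominate — and an exact tie reports "none".

## Annotation

Consequences are computed per transcript and reduced by severity
(stop_lost > missense > stop_retained > synonymous > 5′UTR > 3′UTR >
non-coding exonic > intronic); intronic calls split by transcript biotype.
The transcript-selection rule is "most severe" since no canonical flag
exists in the toy models. HGVS coding positions are 1-based on the coding
strand; protein changes use single-letter amino acids (`p.Y62C`), `p.X123=`
for synonymous, and the c.-string decoder is round-trip tested on both
strands. stop_retained is kept as a distinct category so the category set
stays closed.

## The simulator

The generator emulates the targeted study design: two groups
(control/FDM) × 6 samples, single-end 100 nt reads at ~50× mean depth,
uniform substitution errors at 0.002 with per-base qualities drawn from two
bins (Q38/Q15, 10% low) so the quality filter is non-trivial. The genome
backbone is run-free (no homopolymer ≥ 5 nt) by construction; homopolymer
runs, simple repeats and B1/B2-family repeat copies are embedded
deliberately and recorded, so a run-length scan of the emitted FASTA
reproduces the recorded homopolymer track exactly. Genes are built from
designed mRNAs (CDS divisible by 3, terminal stop, no internal stops) split
into exons on both strands, plus a handful of non-coding transcripts and one
mitochondrial gene.

Planted truth classes: null editing sites at levels U(0.02, 0.30) equal in
both groups; DRE sites at 5% (control) vs 20% (FDM), matching the design the
recovery checks assume; het/hom SNPs at AAF 0.5/1.0; and one artifact class
per removal filter, each placed to violate exactly that filter. Editing-site
positions are drawn with an ADAR-like context bias (weight 2 for G at +1 and
for non-G at −1 on the coding strand), which the motif matrix must recover.
All planted SNPs are emitted in the known-SNP VCF — in an inbred strain the
catalogue coverage of germline variants is essentially complete — so the
expected removal reason for SNP classes is the known-SNP filter; at 50×
depth the 40–60% AAF band alone is statistically unreliable for
heterozygotes (binomial noise puts ~10% of samples outside the band), which
is why that filter is exercised on crafted AAF vectors in unit tests
instead.

Randomness uses numpy `SeedSequence`-style keyed streams: `[seed, k]` per
stage and `[seed, 1000+i]` per sample, giving per-sample independence and
byte-identical reruns.

What the simulator does **not** emulate: splice-aware reads across
junctions, paired ends, position-dependent or context-dependent error
profiles, mapping ambiguity, transcript-abundance-weighted coverage, and
overlapping genes. Passing recovery tests therefore demonstrates the
correctness of the calling/filtering/testing logic under the stated
binomial model, not robustness to alignment pathology in real data.

## Problem sizes and numerics

Default synthetic scale: 3 × 32 kb chromosomes + 3 kb chrM, ~42 genes,
~550 k reads across 12 samples; a full pipeline run takes well under a
minute. Statistical calibration uses 2,000 count-level null sites; exact
tests are swept against brute-force oracles (hypergeometric enumeration, BH
step-up) over exhaustive small-table grids in the test suite and random
sweeps in the acceptance script. LRT statistics are clipped at 0 against
floating-point negatives; BH re-inserts missing values as missing; PCA
centres but does not scale editing levels (they share the [0,1] scale, and
scaling would inflate near-constant sites) and reports variance fractions
from the SVD of the centred matrix. The Venn "presence" rule (level ≥ 1% in
≥ 1 sample of the group) mirrors the pipeline's 1% detection floor. The
top-k DRE table ranks by GLM p (defined for all sites), breaking ties by
Fisher p then coordinate for a deterministic order.

## Known limitations

Single transcript per gene in the simulator (multi-transcript precedence is
unit-tested on crafted models); no covariate adjustment or paired-eye
design in the GLM; no hyper-editing cluster detection; C-to-U and other
editing types out of scope; BAM/CRAM inputs are not parsed (SAM only in the
bundled loader, though pysam underlies it).
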