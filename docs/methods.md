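# Methods

## Experimental model

The package analyses a two-parent cross design for mapping a recessive
monogenic trait. A mutant line (P1, genotype *aa*) is crossed to a
genetically distant wild-type line (P2, *AA*); the F1 is selfed to give an
F2 in which the trait segregates 3 normal : 1 mutant. Four DNA pools are
sequenced: the two parents (20 plants each) and two phenotype-selected F2
bulks of 50 plants. Selection on phenotype skews bulk allele frequencies
near the causal locus — the mutant bulk is fixed for the P1 allele, the
normal bulk carries it at expected frequency 1/3 — and the analysis finds
where that skew exceeds sampling noise.

Throughout, "A" denotes the mutant-parent allele, coordinates are 1-based
inclusive (VCF/GFF3 convention), and the SNP-index is oriented as the
fraction of reads carrying the P1 allele, so the mutant bulk's index rises
to 1 near the locus. Δ(SNP-index) is unsigned (largest − smallest) by
default; a signed variant (MS − MF) is available behind a flag.

## Per-site statistics and filtering

`snp_index` is allele depth of the P1 allele over total depth; sites are
oriented per site by the P1 pool's majority allele. `filter_sites` keeps a
site when every pool reaches `min_depth` (default 8 reads) and the parents
are fixed for opposite alleles at `parent_purity` (default 0.9). Both
thresholds are exposed; the defaults are ordinary QTL-seq practice for
~19x pools — strict enough to drop miscalled and repetitive sites, loose
enough to survive Poisson depth fluctuation. Zero-depth sites are dropped,
never imputed.

## Windows and the simulated null bound

Window geometry is 1 Mb width advancing in 10 kb steps, starting at
position 1 and truncated at the chromosome end; windows with fewer than
`min_snps` (default 3) sites are reported as missing. The window statistic
is the arithmetic mean of per-site Δ.

The null distribution of Δ at a site depends on its two bulk depths, so
confidence bounds are Monte-Carlo simulated conditional on the observed
depth pair (`NullBoundSimulator`): each replicate draws each bulk's true
allele frequency as the mean dosage of 50 plants sampled from 1:2:1 F2
genotype probabilities — equivalently Binomial(2·50, ½)/100 — then
binomial read counts at the observed depths, and recomputes Δ; the bound
is the empirical upper q-quantile (q = 0.99, n_sim = 10,000 by default;
the calibration checks use 100,000 for a tighter quantile estimate).
Bounds are memoized by integer depth pair, and every (side, depth) read
draw uses its own child generator so results are independent of query
order. Replicate bulk frequencies are shared across depth pairs, which
makes a genome scan's ~1,000 distinct pairs cheap.

Per-site bounds are averaged within each window and compared with the
window's mean Δ (per-window comparison of per-site bounds, the common
QTL-seq construction). Since Δ is unsigned, the bound is one-sided upper
by construction. Maximal runs of overlapping or adjacent significant
windows are merged into candidate regions; region boundaries are the
first and last SNP positions inside the merged span (position resolution,
finer than the 10 kb grid), the size is `end − start`, and Kb sizes are
truncated toward zero, matching how such coordinates are conventionally
printed. Regions with fewer than two SNPs have no physical span and are
dropped.

A knife-edge worth knowing: at equal bulk depths d the null Δ is supported
on k/d, and at d = 19 the null CDF at 8/19 is ≈ 0.990, so the 99% quantile
sits exactly on an atom boundary and independent simulations legitimately
return either 8/19 or 9/19. Depth variation across sites (Poisson) makes
most depth pairs unequal and fine-grained, which is why site-level
exceedance of the 99% bound calibrates to ~1% overall.

## Fine mapping

`segregation_test` is Pearson's χ² goodness of fit (no continuity
correction, df = classes − 1) against an expected ratio such as 3:1 or
1:1. `count_recombinants` counts *plants* whose marker genotype is
impossible under complete linkage (mutant-phenotype plants not AA;
normal-phenotype plants AA); counting plants rather than chromosomes is
deliberate — a normal AA plant implies at least one recombinant gamete
but the exact number is unknowable. Missing genotypes (`--`) are skipped
and tallied. `flanking_interval` takes the minimum-count markers as the
core and picks the nearest marker on each side with a count above the
minimum; a side with no such marker is an error naming the uncovered
side. Genetic distance in cM is deliberately not computed: it requires
multipoint map construction, which is out of scope, and printed
recombinant counts do not determine it.

## Variant effects

CDS variants are located by strand-aware transcript offset; the alternate
base (reverse-complemented for minus-strand genes) is substituted into
its codon and both codons are translated with the standard nuclear code
(via Biopython). Changes are reported three-letter style with 1-based
residue numbers (Tyr420Asp). Non-CDS exon hits are "UTR-like", positions
within 2 bp of an exon/intron junction carry an informational
`near_splice` flag, and indels are reported as unclassified. Gene models
whose total CDS length is not a whole number of codons are flagged at
read time and excluded from effect calls. `rank_candidates` orders genes
by worst consequence (non-synonymous > synonymous > intron/UTR-like >
none) with stable order on ties and an explicit `conclusive = False` when
no coding variant separates the genes.

## The simulator

`simulate_f2` builds each plant from two independent F1 gametes; each
gamete is a mosaic of the two parental haplotypes with crossover counts
Poisson at the chromosome's map length (Haldane model, no interference —
the simplest model adequate for testing the statistics) and uniform
breakpoints. Defaults: one 10 Mb chromosome with 10,000 uniformly spaced
SNPs (a single SNP-dense chromosome exercises every statistic; a full
multi-chromosome genome adds nothing), recombination 3.0 cM/Mb (a
cucumber-like genome-wide average), 600 F2 plants, bulks of 50, parental
pools of 20, mean pooled depth 19x, per-read miscall rate 0.002
(configurable; typical of filtered short-read data). The causal position
defaults to 2.5 Mb and is inserted among the markers so exactness checks
(mutant bulk index = 1 with zero error rate) can target it.
`simulate_testcross` forces one gamete to the P1 haplotype, giving 1:1
segregation. Pooled sequencing draws total depth Poisson(19) per site and
reads binomial at the pool's true allele frequency with error flips;
plants are assumed to contribute equal DNA mass. All randomness flows
from one integer seed through named child generators, so every artifact
is byte-reproducible.

`simulate_null_sites` provides a no-QTL table whose sites are
*independent* (each site draws its own bulks from 1:2:1). This exists
because the site-level calibration check — "1% of sites exceed the 99%
bound, within binomial error" — presumes independent sites; on a linked
chromosome all sites share one bulk of 50 plants, so bulk-frequency noise
is correlated over centimorgan scales and the binomial standard error is
wrong there. Region-level false-positive checks use the full linked
genome pipeline, where that correlation is part of the phenomenon being
controlled.

What the generator does not emulate: mapping bias and paralogy,
depth-dependent error profiles, structural variants, segregation
distortion, incomplete penetrance, multi-QTL architectures, and real
marker ascertainment. Passing tests therefore demonstrate correctness of
the statistics under the stated sampling model, not robustness to every
artifact of real resequencing data.

## Problem sizes and numerics

The packaged checks run the scan at 10,000 sites per genome, 20 seeded
replicates for recovery rates, 10 no-QTL genomes for false-positive
regions, and 2,553 plants × 7 markers × 20 replicates for fine mapping —
sizes chosen so the full suite completes in well under a minute while
keeping Monte-Carlo error far from the asserted margins. Null-bound
memoization is shared across replicates (the bound is a property of the
depth pair, not the dataset). Quantiles use numpy's default linear
interpolation; depth keys are rounded to integers; windows with ties at
boundaries follow closed-interval membership (`start ≤ pos ≤ end`).

## Known limitations

Single-chromosome region calling (no genome-wide FDR across
chromosomes); boxcar window mean only (no tricube/loess smoothing of
published QTL-seq figures); no indel consequence logic; no UTR phasing;
the synthetic candidate gene stands in for a real annotation, with
coordinates that are internally consistent but arbitrary.
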