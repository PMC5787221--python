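# bsamap

Bulked-segregant QTL-seq mapping of monogenic traits: pooled SNP-index
statistics with depth-conditioned simulated confidence bounds, sliding-window
candidate-region calling, F2 recombinant fine mapping, and variant-effect
candidate-gene screening — together with a forward simulator of the whole
experiment.

## Who this is for

Plant geneticists mapping a Mendelian locus (here, a recessive genic male
sterility gene in a cucumber F2) from four pooled resequencing libraries:
the two parental lines (P1, the mutant parent; P2, the fertile parent) and
two phenotype-selected bulks of F2 plants (MF, male fertile; MS, male
sterile). The package takes a variant table with per-pool allele depths and
carries the analysis from raw allele counts to a short list of candidate
genes; it does not do read alignment or variant calling.

## The statistics

At a biallelic SNP, the **SNP-index** of a pool is the fraction of its reads
carrying the mutant-parent allele,

    SNP-index = depth(P1 allele) / total depth,

and the contrast between bulks is

    Δ(SNP-index) = SNP-index_largest − SNP-index_smallest ∈ [0, 1].

For a fully linked recessive locus the sterile bulk is fixed for the mutant
allele (index = 1) while fertile F2 plants are 2 heterozygous : 1 homozygous
wild type, so the fertile bulk's expectation is 1/3 and E[Δ] ≈ 2/3; at
unlinked sites E[Δ] → 0. Sites are screened by pool depth and by parental
consistency (each parent pool fixed, for opposite alleles). Δ is averaged in
1 Mb windows advancing 10 kb. Because the null spread of Δ depends on read
depth, a 99% upper bound is simulated per observed depth pair: each
replicate draws two bulks of 50 plants from 1:2:1 F2 genotype probabilities
and binomial read counts at the observed depths. Runs of windows whose mean
Δ exceeds the averaged bound are merged into candidate regions, delimited by
their first and last SNP.

Fine mapping then scores individual F2 plants at SNP markers: a sterile
plant not typed AA, or a fertile plant typed AA, is a recombinant; the
nearest markers on either side of the zero-recombinant core that still show
recombinants delimit the locus. Variants inside that interval are classified
against gene models (synonymous / non-synonymous / intron / UTR-like) by
strand-aware codon substitution, and genes are ranked by worst consequence.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_fine_mapping.py` (2,553 simulated F2 plants, 7 markers
around a causal locus at 2.5 Mb) prints:

```
marker_id     pos  n_recombinants
G2350236C 2350236              13
A2440245C 2440245               4
C2480249T 2480249               3
C2515252G 2515252               0
A2550256G 2550256               2
C2610262T 2610262               6
T2700271A 2700271              13
locus delimited to C2480249T .. A2550256G: 70,007 bp = 70 Kb
```

Recombinant counts fall towards the locus and the flanking markers pin it
to a 70 Kb interval containing the true position. The genome-scan example
(`02_delta_snp_index_scan.py`) prints the called candidate region and
writes the classic Δ(SNP-index) plot with the 99% bound overlaid; the
candidate-gene example (`04_candidate_gene.py`) translates a 1,995 bp CDS
into a 664-residue protein and reports its single coding lesion as
`Tyr420Asp (codon 420), non-synonymous`.

The same pipeline is scriptable from the shell:

```
bsamap simulate --seed 1 --out-dir out/sim
bsamap bsa --vcf out/sim/pools.vcf --out-dir out/bsa --chrom-length 10000000
bsamap finemap --genotypes out/sim/f2_genotypes.tsv --out-dir out/fm
```

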