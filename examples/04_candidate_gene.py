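"""Candidate-gene screening: translate the CDS and classify the lesion.

Uses the synthetic 3-exon candidate gene (1,995 bp CDS) and its single
coding substitution, then ranks genes of the interval by consequence.
"""

import bsamap as bm
from bsamap.annotate import _cds_sequence

genome, gene, variant = bm.make_candidate_gene(seed=0)
protein = bm.translate_cds(_cds_sequence(gene, genome))
print(f"CDS length: {gene.cds_length} bp -> protein of {len(protein)} residues")

effect = bm.classify_variant(variant, gene, genome)
chrom, pos, ref, alt = variant
print(f"variant {chrom}:{pos} {ref}>{alt}: {effect.region}, {effect.consequence}")
print(f"amino-acid change: {effect.aa_change} (codon {effect.codon_number})")
print("  (a tyrosine-to-aspartate change in the third exon: the kind of")
print("   non-synonymous lesion that nominates a gene as the causal candidate)")

effects = bm.annotate_variants([variant], [gene], genome)
report = bm.rank_candidates(effects, [gene.gene_id, "NeighborGeneA", "NeighborGeneB"])
print(report.table[["gene_id", "n_variants", "worst_consequence", "aa_changes"]]
      .to_string(index=False))
print(f"conclusive candidate: {report.conclusive}")
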