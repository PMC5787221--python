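"""Fine mapping: recombinant counts at 7 markers in 2,553 F2 plants.

A plant is recombinant at a marker when its genotype contradicts its
phenotype under complete linkage (sterile but not AA, or fertile AA).
The flanking markers — nearest markers on each side of the
zero-recombinant core that still show recombinants — delimit the locus.
"""

import bsamap as bm
from bsamap.finemap import scan_markers
from bsamap.simulate import finemap_marker_indices

config = bm.SimConfig(seed=1, n_f2=2_553)
pop = bm.simulate_f2(config)
table = pop.to_f2_table(finemap_marker_indices(pop))

markers, counts = scan_markers(table, chrom=config.chrom)
print(counts[["marker_id", "pos", "n_recombinants"]].to_string(index=False))
print("  (counts rise with distance from the locus; zero-count markers are")
print("   fully linked at this population size)")

interval = bm.flanking_interval(markers, list(counts["n_recombinants"]))
print(
    f"locus delimited to {interval.left.marker_id} .. {interval.right.marker_id}: "
    f"{interval.span_bp:,} bp = {interval.span_kb} Kb"
)
print(f"  (simulated causal position: {config.causal_pos:,} — inside the interval)")
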