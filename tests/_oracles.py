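"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, a hand-typed codon table) and shares no code path with bsamap.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Standard nuclear genetic code, typed out by hand.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


def oracle_chi2(observed, ratio):
    """Pearson goodness-of-fit from the definition, Σ(O−E)²/E."""
    total = sum(observed)
    s = sum(ratio)
    chi2 = 0.0
    for o, r in zip(observed, ratio):
        e = total * r / s
        chi2 += (o - e) ** 2 / e
    return chi2


def oracle_cds_effect(variant, gene, genome):
    """Base-by-base transcript reconstruction and hand-table translation.

    Returns (consequence, codon_number, aa_change_3letter) for CDS hits,
    else None.
    """
    chrom, pos, ref, alt = variant
    seq = genome[chrom]
    coords = []
    for s, e in sorted(gene.cds):
        coords.extend(range(s, e + 1))
    if gene.strand == "-":
        coords = coords[::-1]
    bases = []
    for c in coords:
        b = seq[c - 1]
        bases.append(b if gene.strand == "+" else COMP[b])
    if pos not in coords:
        return None
    i = coords.index(pos)
    mutated = list(bases)
    mutated[i] = alt if gene.strand == "+" else COMP[alt]
    ci = i // 3
    aa_ref = CODON_TABLE["".join(bases[3 * ci : 3 * ci + 3])]
    aa_alt = CODON_TABLE["".join(mutated[3 * ci : 3 * ci + 3])]
    if aa_ref == aa_alt:
        return ("synonymous", ci + 1, None)
    return ("non-synonymous", ci + 1, f"{AA3[aa_ref]}{ci + 1}{AA3[aa_alt]}")


def oracle_filter(sites, min_depth, parent_purity):
    """Row-by-row re-check of the site filter."""
    kept = []
    for s in sites:
        ok = True
        for pool in ("P1", "P2", "MF", "MS"):
            r, a = s.depths[pool]
            if r + a < min_depth:
                ok = False
        if not ok:
            continue
        r1, a1 = s.depths["P1"]
        p1_is_alt = a1 > r1
        f1 = (a1 if p1_is_alt else r1) / (r1 + a1)
        r2, a2 = s.depths["P2"]
        f2 = (a2 if p1_is_alt else r2) / (r2 + a2)
        if f1 >= parent_purity and f2 <= 1 - parent_purity:
            kept.append(s)
    return kept


def oracle_window_means(positions, deltas, windows):
    """Naive double loop over windows and sites."""
    out = []
    for start, end in windows:
        vals = [d for p, d in zip(positions, deltas) if start <= p <= end]
        out.append((len(vals), sum(vals) / len(vals) if vals else float("nan")))
    return out


def oracle_null_bound(depth_mf, depth_ms, bulk_size, n_sim, q, seed):
    """Second, independently coded null simulation for the delta bound."""
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_sim)
    for k in range(n_sim):
        geno_mf = rng.choice([0, 1, 2], size=bulk_size, p=[0.25, 0.5, 0.25])
        geno_ms = rng.choice([0, 1, 2], size=bulk_size, p=[0.25, 0.5, 0.25])
        f_mf = geno_mf.mean() / 2.0
        f_ms = geno_ms.mean() / 2.0
        i_mf = rng.binomial(depth_mf, f_mf) / depth_mf
        i_ms = rng.binomial(depth_ms, f_ms) / depth_ms
        deltas[k] = abs(i_mf - i_ms)
    return float(np.quantile(deltas, q))


def oracle_recombinants(phenotypes, genotypes):
    """Direct bookkeeping: impossible phenotype/genotype combinations."""
    n = 0
    for ph, g in zip(phenotypes, genotypes):
        if g == "--":
            continue
        if ph == "sterile" and g != "AA":
            n += 1
        if ph == "fertile" and g == "AA":
            n += 1
    return n


def oracle_overlap(interval, genes):
    """Inclusive-overlap scan for gene spans."""
    chrom, start, end = interval
    hits = []
    for gene_id, gchrom, s, e in genes:
        if gchrom == chrom and not (e < start or s > end):
            hits.append(gene_id)
    return hits
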