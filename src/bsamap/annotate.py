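"""Variant-effect classification against gene models and candidate ranking.

A single-base variant is located within a gene model using strand-aware
transcript coordinates; for CDS hits the alternate base is substituted
into its codon and both codons are translated with the standard nuclear
genetic code. Amino-acid changes are reported in three-letter notation
with 1-based protein positions (e.g. Tyr420Asp). Variants in exon
sequence outside any CDS interval are labelled "UTR-like" rather than
guessed as 5'/3' UTR, since annotations may lack explicit UTR features.
Indels are reported but not classified (frameshift logic is out of
scope). Proximity to a splice junction (±2 bp into the intron) is flagged
informationally, not treated as a consequence class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import AnnotationError
from .io import GeneModel, revcomp

log = logging.getLogger(__name__)

#: Consequence severity for candidate ranking (higher = more damaging).
_SEVERITY = {
    "non-synonymous": 3,
    "synonymous": 2,
    "intron": 1,
    "UTR-like": 1,
    "indel-unclassified": 1,
    "intergenic": 0,
}


@dataclass(frozen=True)
class VariantEffect:
    """A variant's consequence on one gene model (or intergenic)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    region: str  # intergenic | intron | CDS | UTR-like
    consequence: str | None  # synonymous | non-synonymous | indel-unclassified
    aa_change: str | None = None  # e.g. Tyr420Asp; set iff non-synonymous
    codon_number: int | None = None
    near_splice: bool = False

    @property
    def severity(self) -> int:
        if self.consequence in _SEVERITY:
            return _SEVERITY[self.consequence]
        return _SEVERITY.get(self.region, 0)


@dataclass(frozen=True)
class TranslationResult:
    protein: str  # terminal stop excluded
    starts_with_met: bool
    has_terminal_stop: bool
    premature_stop_codon: int | None  # 1-based codon index of an internal stop

    def __len__(self) -> int:
        return len(self.protein)


def translate_cds(cds_sequence: str) -> TranslationResult:
    """Translate a CDS with the standard nuclear code.

    Length must be divisible by 3. The terminal stop is excluded from the
    protein; a missing ATG start or terminal stop is warned about; an
    internal stop is flagged with its 1-based codon index.
    """
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise AnnotationError(f"CDS length {len(seq)} is not divisible by 3")
    aa = str(Seq(seq).translate())
    starts_with_met = aa.startswith("M")
    if not starts_with_met:
        log.warning("CDS does not start with ATG")
    has_terminal_stop = aa.endswith("*")
    protein = aa[:-1] if has_terminal_stop else aa
    if not has_terminal_stop:
        log.warning("CDS does not end with a stop codon")
    premature = protein.find("*")
    return TranslationResult(
        protein,
        starts_with_met,
        has_terminal_stop,
        premature + 1 if premature != -1 else None,
    )


def _cds_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Spliced CDS, 5'→3' in transcript orientation."""
    chrom_seq = genome[gene.chrom]
    parts = []
    for s, e in gene.cds:
        piece = chrom_seq[s - 1 : e]
        parts.append(piece if gene.strand == "+" else revcomp(piece))
    return "".join(parts)


def _transcript_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of genomic ``pos`` within the spliced CDS, or None."""
    acc = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            return acc + (pos - s if gene.strand == "+" else e - pos)
        acc += e - s + 1
    return None


def _near_splice(gene: GeneModel, pos: int) -> bool:
    """Within 2 bp outside an internal exon boundary (i.e. in splice sites)."""
    exons = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 < pos <= e1 + 2 or s2 - 2 <= pos < s2:
            return True
    return False


def classify_variant(
    variant: tuple[str, int, str, str],
    gene: GeneModel,
    genome: Mapping[str, str],
) -> VariantEffect:
    """Classify one variant against one gene model.

    The REF allele is checked against the genome sequence (mismatch is
    fatal: it indicates inconsistent inputs). Positions outside the gene
    span are intergenic; inside the span but outside exons, intronic; in
    an exon but outside the CDS, UTR-like; in the CDS, synonymous or
    non-synonymous by codon substitution and translation.
    """
    chrom, pos, ref, alt = variant
    if chrom not in genome:
        raise AnnotationError(f"chromosome {chrom!r} not in genome")
    chrom_seq = genome[chrom]
    if not 1 <= pos <= len(chrom_seq):
        raise AnnotationError(f"position {pos} outside chromosome {chrom}")
    if len(ref) == 1 and chrom_seq[pos - 1] != ref.upper():
        raise AnnotationError(
            f"REF mismatch at {chrom}:{pos}: variant says {ref!r}, "
            f"genome has {chrom_seq[pos - 1]!r}"
        )

    if len(ref) != 1 or len(alt) != 1:
        region = _locate_region(gene, pos)
        gene_id = gene.gene_id if region != "intergenic" else None
        return VariantEffect(
            chrom, pos, ref, alt, gene_id, region, "indel-unclassified",
            near_splice=_near_splice(gene, pos),
        )

    if gene.chrom != chrom:
        return VariantEffect(chrom, pos, ref, alt, None, "intergenic", None)
    region = _locate_region(gene, pos)
    if region == "intergenic":
        return VariantEffect(chrom, pos, ref, alt, None, "intergenic", None)
    if region != "CDS":
        return VariantEffect(
            chrom, pos, ref, alt, gene.gene_id, region, None,
            near_splice=_near_splice(gene, pos),
        )

    if not gene.coding_frame_ok:
        raise AnnotationError(
            f"gene {gene.gene_id} CDS length {gene.cds_length} not divisible by 3"
        )
    off = _transcript_offset(gene, pos)
    assert off is not None
    cds_seq = _cds_sequence(gene, genome)
    codon_idx = off // 3
    codon_pos = off % 3
    codon = cds_seq[3 * codon_idx : 3 * codon_idx + 3]
    alt_t = alt.upper() if gene.strand == "+" else revcomp(alt.upper())
    mutated = codon[:codon_pos] + alt_t + codon[codon_pos + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        consequence, aa_change = "synonymous", None
    else:
        consequence = "non-synonymous"
        aa_change = f"{seq3(aa_ref)}{codon_idx + 1}{seq3(aa_alt)}"
    return VariantEffect(
        chrom, pos, ref, alt, gene.gene_id, "CDS", consequence,
        aa_change=aa_change, codon_number=codon_idx + 1,
        near_splice=_near_splice(gene, pos),
    )


def _locate_region(gene: GeneModel, pos: int) -> str:
    lo, hi = gene.span
    if not lo <= pos <= hi:
        return "intergenic"
    if any(s <= pos <= e for s, e in gene.cds):
        return "CDS"
    if any(s <= pos <= e for s, e in gene.exons):
        return "UTR-like"
    return "intron"


def annotate_variants(
    variants: Sequence[tuple[str, int, str, str]],
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[VariantEffect]:
    """Classify each variant against every overlapping (valid) gene model.

    Variants overlapping no gene yield a single intergenic effect. Gene
    models with an invalid coding frame are skipped with a warning.
    """
    effects: list[VariantEffect] = []
    for variant in variants:
        chrom, pos = variant[0], variant[1]
        hit = False
        for gene in models:
            if gene.chrom != chrom:
                continue
            lo, hi = gene.span
            if not lo <= pos <= hi:
                continue
            if gene.cds and not gene.coding_frame_ok:
                log.warning(
                    "skipping gene %s for %s:%d (invalid coding frame)",
                    gene.gene_id, chrom, pos,
                )
                continue
            effects.append(classify_variant(variant, gene, genome))
            hit = True
        if not hit:
            ref, alt = variant[2], variant[3]
            cons = "indel-unclassified" if len(ref) != 1 or len(alt) != 1 else None
            effects.append(
                VariantEffect(chrom, pos, ref, alt, None, "intergenic", cons)
            )
    return effects


@dataclass
class CandidateReport:
    """Genes of an interval ordered by worst variant consequence."""

    table: pd.DataFrame  # gene_id, n_variants, worst_consequence, aa_changes, severity
    conclusive: bool  # False when no coding variant distinguishes the genes


def rank_candidates(
    effects: Sequence[VariantEffect], gene_ids: Sequence[str]
) -> CandidateReport:
    """Order interval genes by severity: non-synonymous > synonymous >
    intronic/UTR-like > none. Ties are preserved (stable order, no invented
    tiebreak); with no coding variant at all the report is inconclusive.
    """
    per_gene: dict[str, list[VariantEffect]] = {g: [] for g in gene_ids}
    for eff in effects:
        if eff.gene_id in per_gene:
            per_gene[eff.gene_id].append(eff)
    rows = []
    for gene_id in gene_ids:
        effs = per_gene[gene_id]
        worst = max((e.severity for e in effs), default=0)
        worst_label = next(
            (
                e.consequence or e.region
                for e in sorted(effs, key=lambda e: -e.severity)
            ),
            "none",
        )
        aa = ";".join(e.aa_change for e in effs if e.aa_change) or ""
        rows.append((gene_id, len(effs), worst_label if effs else "none", aa, worst))
    df = pd.DataFrame(
        rows, columns=["gene_id", "n_variants", "worst_consequence", "aa_changes", "severity"]
    )
    df = df.sort_values("severity", ascending=False, kind="stable").reset_index(drop=True)
    conclusive = bool((df["severity"] >= 2).any())
    return CandidateReport(df, conclusive)


def effects_table(effects: Sequence[VariantEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.chrom, e.pos, e.ref, e.alt, e.gene_id or "", e.region,
                e.consequence or "", e.aa_change or "", e.near_splice,
            )
            for e in effects
        ],
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "region",
            "consequence", "aa_change", "near_splice",
        ],
    )
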