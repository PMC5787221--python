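"""Segregation tests, recombinant counting and flanking-interval delimitation.

For a recessive trait scored in an F2, a plant is a *recombinant* at a
marker when its marker genotype is impossible under complete linkage:
a sterile plant (aa at the locus) typed AB or BB, or a fertile plant
typed AA (A = mutant-parent allele). Counting is per plant, not per
chromosome — a fertile AA plant implies at least one recombinant gamete
but the exact number is unknowable, which matches the small integer
counts such experiments report. The flanking markers are the nearest
markers on either side of the minimum-recombinant core that still show
recombinants; they delimit the mapped interval, whose physical span is
reported in truncated Kb. Genetic distance in cM is deliberately not
computed (it requires multipoint map construction, out of scope here).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FineMapError
from .io import GENOTYPE_CODES, MISSING_CODE, GeneModel

log = logging.getLogger(__name__)

_MARKER_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


@dataclass(frozen=True)
class MarkerDef:
    """A SNP genotyping marker. Ids follow the <P2 base><pos><P1 base> style
    (e.g. T785241C), the convention used for allele-specific PCR markers."""

    marker_id: str
    chrom: str
    pos: int
    allele_P1: str
    allele_P2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("marker pos must be >= 1")
        if self.allele_P1 == self.allele_P2:
            raise ValueError("marker alleles must differ")


def parse_marker_id(marker_id: str, chrom: str = "chr3") -> MarkerDef:
    """Parse ids like ``T785241C``: leading base, position, trailing base.

    The leading base is taken as the P2 (reference) allele and the trailing
    base as the P1 (mutant-parent) allele.
    """
    m = _MARKER_RE.match(marker_id)
    if not m:
        raise FineMapError(f"cannot parse marker id {marker_id!r}")
    ref, pos, alt = m.groups()
    return MarkerDef(marker_id, chrom, int(pos), allele_P1=alt, allele_P2=ref)


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    ratio: tuple[float, ...]
    chi2: float
    df: int
    p_value: float


def segregation_test(
    observed: Sequence[int], ratio: Sequence[float]
) -> SegregationResult:
    """Pearson χ² goodness-of-fit of class counts to an expected ratio.

    No continuity correction; df = classes − 1. E.g. 948 fertile : 321
    sterile against 3:1 gives χ² ≈ 0.059 (consistent with monogenic
    recessive inheritance).
    """
    observed = tuple(int(x) for x in observed)
    if len(observed) != len(ratio):
        raise FineMapError("observed and ratio must have the same length")
    total = sum(observed)
    if total <= 0:
        raise FineMapError("total count must be positive")
    props = np.asarray(ratio, dtype=float)
    props = props / props.sum()
    expected = total * props
    if np.any(expected <= 0):
        raise FineMapError("expected count of zero in some class")
    chi2, p = sps.chisquare(observed, expected)
    return SegregationResult(
        observed, tuple(expected), tuple(props), float(chi2), len(observed) - 1, float(p)
    )


@dataclass(frozen=True)
class RecombinantCount:
    marker_id: str
    n_recombinants: int
    n_missing: int
    n_plants: int


def count_recombinants(f2_table: pd.DataFrame, marker_id: str) -> RecombinantCount:
    """Count plants whose genotype at ``marker_id`` contradicts their phenotype.

    Sterile plants typed AB or BB and fertile plants typed AA are
    recombinant; ``--`` genotypes are skipped and tallied as missing.
    """
    if marker_id not in f2_table.columns:
        raise FineMapError(f"marker {marker_id!r} not in F2 table")
    geno = f2_table[marker_id].to_numpy()
    pheno = f2_table["phenotype"].to_numpy()
    unknown = set(geno) - set(GENOTYPE_CODES) - {MISSING_CODE}
    if unknown:
        raise FineMapError(f"unknown genotype code(s) {sorted(unknown)} at {marker_id}")
    missing = geno == MISSING_CODE
    sterile = pheno == "sterile"
    rec = (~missing) & (
        (sterile & (geno != "AA")) | (~sterile & (geno == "AA"))
    )
    return RecombinantCount(
        marker_id, int(rec.sum()), int(missing.sum()), int(len(geno) - missing.sum())
    )


def scan_markers(
    f2_table: pd.DataFrame, chrom: str = "chr3"
) -> tuple[list[MarkerDef], pd.DataFrame]:
    """Count recombinants for every marker column, sorted by position."""
    marker_cols = [c for c in f2_table.columns if c not in ("plant_id", "phenotype")]
    markers = sorted(
        (parse_marker_id(c, chrom) for c in marker_cols), key=lambda m: m.pos
    )
    rows = []
    for m in markers:
        rc = count_recombinants(f2_table, m.marker_id)
        rows.append((m.marker_id, m.pos, rc.n_recombinants, rc.n_missing, rc.n_plants))
    table = pd.DataFrame(
        rows, columns=["marker_id", "pos", "n_recombinants", "n_missing", "n_plants"]
    )
    return markers, table


@dataclass(frozen=True)
class FlankingInterval:
    left: MarkerDef
    right: MarkerDef
    span_bp: int

    @property
    def span_kb(self) -> int:
        """Physical span in Kb, truncated toward zero."""
        return self.span_bp // 1000

    @property
    def start(self) -> int:
        return self.left.pos

    @property
    def end(self) -> int:
        return self.right.pos


def flanking_interval(
    markers: Sequence[MarkerDef], counts: Sequence[int]
) -> FlankingInterval:
    """Delimit the locus by the closest markers still showing recombinants.

    The minimum-recombinant markers form the core; the left flank is the
    rightmost marker left of the core with a count above the minimum, the
    right flank the symmetric choice. Both sides must be covered.
    """
    if len(markers) != len(counts) or not markers:
        raise FineMapError("need parallel non-empty markers and counts")
    order = np.argsort([m.pos for m in markers], kind="stable")
    markers = [markers[i] for i in order]
    counts = [counts[i] for i in order]
    min_count = min(counts)
    core = [i for i, c in enumerate(counts) if c == min_count]
    core_lo, core_hi = core[0], core[-1]
    left_candidates = [
        i for i in range(core_lo) if counts[i] > min_count
    ]
    right_candidates = [
        i for i in range(core_hi + 1, len(markers)) if counts[i] > min_count
    ]
    if not left_candidates and not right_candidates:
        raise FineMapError(
            "no marker with excess recombinants on either side of the core; "
            "cannot delimit the locus"
        )
    if not left_candidates:
        raise FineMapError("no flanking marker on the left side of the core")
    if not right_candidates:
        raise FineMapError("no flanking marker on the right side of the core")
    left = markers[left_candidates[-1]]
    right = markers[right_candidates[0]]
    return FlankingInterval(left, right, right.pos - left.pos)


def interval_genes(
    chrom: str, start: int, end: int, models: Sequence[GeneModel]
) -> list[str]:
    """Gene ids whose genomic span overlaps [start, end], inclusive."""
    hits = []
    for m in models:
        s, e = m.span
        if m.chrom == chrom and s <= end and e >= start:
            hits.append(m.gene_id)
    return hits
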