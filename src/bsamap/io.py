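"""Readers and writers for the formats the pipeline touches.

All genomic coordinates in this package are 1-based inclusive, matching
VCF and GFF3. Any half-open arithmetic is internal and never serialized.

The canonical variant input is a VCF 4.x with a per-sample ``AD`` (allele
depth) FORMAT field for the four pools P1 (mutant parent), P2 (fertile
parent), MF (male-fertile bulk) and MS (male-sterile bulk). A flat
tab-separated dialect with one depth pair per pool is accepted as an
equivalent representation, because the unit of analysis is the variant
table, not reads.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, FormatError

log = logging.getLogger(__name__)

#: Canonical pool order: mutant parent, fertile parent, fertile bulk, sterile bulk.
POOLS: tuple[str, str, str, str] = ("P1", "P2", "MF", "MS")

_BASES = frozenset("ACGT")

GENOTYPE_CODES = ("AA", "AB", "BB")
MISSING_CODE = "--"
PHENOTYPES = ("fertile", "sterile")


@dataclass(frozen=True)
class PoolSite:
    """One biallelic SNP with per-pool allele depths.

    ``depths`` maps each pool label to a ``(ref_depth, alt_depth)`` pair in
    reads. This is the unit on which the SNP-index statistics operate.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    depths: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for pool, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth for pool {pool}")

    def total_depth(self, pool: str) -> int:
        r, a = self.depths[pool]
        return r + a


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene model (one per transcript).

    ``exons`` are genomic 1-based inclusive intervals in ascending order.
    ``cds`` intervals are ordered 5'→3' in *transcript* orientation: ascending
    genomic start on the plus strand, descending on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def coding_frame_ok(self) -> bool:
        """True when the total CDS length is a whole number of codons."""
        return self.cds_length > 0 and self.cds_length % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covered by the gene's exons."""
        coords = [c for s, e in self.exons for c in (s, e)] or [
            c for s, e in self.cds for c in (s, e)
        ]
        return min(coords), max(coords)


# ---------------------------------------------------------------------------
# Pool variant tables (VCF + TSV dialect)
# ---------------------------------------------------------------------------

def read_pool_vcf(
    path: str | Path,
    pool_names: Sequence[str] = POOLS,
    stats: dict | None = None,
) -> list[PoolSite]:
    """Read biallelic SNPs with per-pool AD depths from a VCF.

    Multiallelic records, indels and records with malformed AD fields are
    skipped; counts of each are logged and, when a ``stats`` dict is passed,
    recorded under ``n_records``, ``n_multiallelic``, ``n_indel``,
    ``n_bad_ad`` and ``n_sites``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [p for p in pool_names if p not in samples]
    if missing:
        raise ConfigError(
            f"pool sample(s) {missing} not found in VCF samples {samples}"
        )
    order = [samples.index(p) for p in pool_names]

    counts = {"n_records": 0, "n_multiallelic": 0, "n_indel": 0, "n_bad_ad": 0}
    sites: list[PoolSite] = []
    for v in vcf:
        counts["n_records"] += 1
        alts = v.ALT
        if len(alts) != 1:
            counts["n_multiallelic"] += 1
            continue
        ref, alt = v.REF.upper(), alts[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            counts["n_indel"] += 1
            continue
        ad = v.format("AD")
        if ad is None or ad.ndim != 2 or ad.shape[1] < 2 or (ad[:, :2] < 0).any():
            counts["n_bad_ad"] += 1
            continue
        depths = {
            pool: (int(ad[i, 0]), int(ad[i, 1]))
            for pool, i in zip(pool_names, order)
        }
        sites.append(PoolSite(v.CHROM, v.POS, ref, alt, depths))

    counts["n_sites"] = len(sites)
    log.info(
        "read %d VCF records: %d sites kept, %d multiallelic, %d indel, %d bad AD",
        counts["n_records"], counts["n_sites"], counts["n_multiallelic"],
        counts["n_indel"], counts["n_bad_ad"],
    )
    if stats is not None:
        stats.update(counts)
    return sites


def write_pool_vcf(
    sites: Iterable[PoolSite],
    path: str | Path,
    pool_names: Sequence[str] = POOLS,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write PoolSites as a minimal VCF 4.2 with GT:AD per pool."""
    sites = list(sites)
    if contig_lengths is None:
        contig_lengths = {}
        for s in sites:
            contig_lengths[s.chrom] = max(contig_lengths.get(s.chrom, 0), s.pos)
    lines = ["##fileformat=VCFv4.2", "##source=bsamap"]
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(pool_names)
    )
    for s in sites:
        cells = [
            s.chrom, str(s.pos), ".", s.ref_allele, s.alt_allele,
            ".", "PASS", ".", "GT:AD",
        ]
        for pool in pool_names:
            r, a = s.depths[pool]
            cells.append(f"./.:{r},{a}")
        lines.append("\t".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


def _tsv_columns(pool_names: Sequence[str]) -> list[str]:
    cols = ["chrom", "pos", "ref", "alt"]
    for pool in pool_names:
        cols += [f"{pool}_ref", f"{pool}_alt"]
    return cols


def write_pool_tsv(
    sites: Iterable[PoolSite],
    path: str | Path,
    pool_names: Sequence[str] = POOLS,
) -> None:
    """Write the flat TSV dialect: one depth pair per pool, single header."""
    rows = []
    for s in sites:
        row = [s.chrom, s.pos, s.ref_allele, s.alt_allele]
        for pool in pool_names:
            row += list(s.depths[pool])
        rows.append(row)
    df = pd.DataFrame(rows, columns=_tsv_columns(pool_names))
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_pool_tsv(
    path: str | Path, pool_names: Sequence[str] = POOLS
) -> list[PoolSite]:
    df = pd.read_csv(path, sep="\t")
    expected = _tsv_columns(pool_names)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"pool TSV is missing columns {missing}")
    sites = []
    for row in df.itertuples(index=False):
        depths = {
            pool: (int(getattr(row, f"{pool}_ref")), int(getattr(row, f"{pool}_alt")))
            for pool in pool_names
        }
        sites.append(PoolSite(str(row.chrom), int(row.pos), row.ref, row.alt, depths))
    return sites


def read_pool_table(
    path: str | Path, pool_names: Sequence[str] = POOLS, stats: dict | None = None
) -> list[PoolSite]:
    """Dispatch on extension: ``.vcf`` → VCF reader, otherwise the TSV dialect."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_pool_vcf(path, pool_names, stats=stats)
    return read_pool_tsv(path, pool_names)


# ---------------------------------------------------------------------------
# Gene models and genome sequence
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, one :class:`GeneModel` per mRNA.

    CDS intervals are returned 5'→3' in transcript orientation. Models whose
    total CDS length is not divisible by 3 are still returned (so they can be
    reported) but carry ``coding_frame_ok == False`` and are excluded from
    effect calls downstream; a warning is logged here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    transcripts = list(db.features_of_type("mRNA")) + list(
        db.features_of_type("transcript")
    )
    if not transcripts:
        # GFF3 without explicit transcript features: genes parent CDS directly.
        transcripts = list(db.features_of_type("gene"))
    for tx in transcripts:
        exons = sorted(
            (f.start, f.end) for f in db.children(tx, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(tx, featuretype="CDS"))
        if not exons:
            exons = list(cds)
        if tx.strand == "-":
            cds = cds[::-1]
        model = GeneModel(tx.id, tx.seqid, tx.strand, tuple(exons), tuple(cds))
        if model.cds and not model.coding_frame_ok:
            log.warning(
                "gene model %s has CDS length %d not divisible by 3; "
                "excluded from effect calls",
                model.gene_id, model.cds_length,
            )
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as a minimal GFF3 (gene/mRNA/exon/CDS)."""
    lines = ["##gff-version 3"]
    for m in models:
        start, end = m.span
        attrs = f"ID=gene:{m.gene_id}"
        lines.append(
            f"{m.chrom}\tbsamap\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{m.chrom}\tbsamap\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id};Parent=gene:{m.gene_id}"
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                f"{m.chrom}\tbsamap\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"
            )
        for i, (s, e) in enumerate(sorted(m.cds), 1):
            lines.append(
                f"{m.chrom}\tbsamap\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                f"ID={m.gene_id}.cds{i};Parent={m.gene_id}"
            )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: uppercase sequence}``; duplicate ids are fatal."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# F2 genotype/phenotype tables (fine mapping input)
# ---------------------------------------------------------------------------

def read_f2_table(path: str | Path) -> pd.DataFrame:
    """Read the fine-mapping table: plant_id, phenotype, one column per marker.

    Genotypes are coded AA/AB/BB with A the mutant-parent (P1) allele and
    ``--`` for missing; phenotypes are ``fertile``/``sterile``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("plant_id", "phenotype"):
        if col not in df.columns:
            raise FormatError(f"F2 table is missing column {col!r}")
    bad_pheno = set(df["phenotype"]) - set(PHENOTYPES)
    if bad_pheno:
        raise FormatError(f"unknown phenotype value(s) {sorted(bad_pheno)}")
    marker_cols = [c for c in df.columns if c not in ("plant_id", "phenotype")]
    allowed = set(GENOTYPE_CODES) | {MISSING_CODE}
    for col in marker_cols:
        bad = set(df[col]) - allowed
        if bad:
            raise FormatError(f"unknown genotype code(s) {sorted(bad)} in {col!r}")
    return df


def write_f2_table(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# Small shared helpers
# ---------------------------------------------------------------------------

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so failed runs leave no partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]
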