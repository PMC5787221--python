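"""Forward simulation of an F2 bulked-segregant sequencing experiment.

The generator emulates the study design the statistics assume: a cross
between a male-sterile mutant line (P1, genotype aa at the causal locus)
and a distinct fertile line (P2, AA), selfing of the F1 to produce an F2
in which sterility segregates 3:1 (recessive, fully penetrant),
phenotype-selected bulks of 50 plants, parental pools of 20 plants, and
pooled Illumina resequencing at ~19x mean depth.

Gametes are mosaics of the two parental haplotypes with crossovers placed
by a no-interference (Haldane) model at a configurable cM/Mb rate. Pooled
read depths are Poisson around the configured mean; each read reports the
pool allele frequency with a small per-read miscall probability.

Throughout, allele "A" denotes the mutant-parent (P1) allele. In the
emitted variant table the P2 allele is REF and the P1 allele is ALT, so a
pool fixed for the fertile-parent haplotype shows alt_depth = 0.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    GENOTYPE_CODES,
    POOLS,
    GeneModel,
    PoolSite,
    atomic_write_text,
    write_f2_table,
    write_pool_vcf,
)

log = logging.getLogger(__name__)

#: Genotype dosage (count of P1 "A" alleles) → AA/AB/BB code, A = P1 allele.
DOSAGE_TO_CODE = {2: "AA", 1: "AB", 0: "BB"}
CODE_TO_DOSAGE = {v: k for k, v in DOSAGE_TO_CODE.items()}


@dataclass
class SimConfig:
    """Parameters of the simulated mapping experiment.

    Defaults mirror the study design: bulks of 50 F2 plants, parental pools
    of 20 plants, ~19x pooled depth, and one SNP-dense 10 Mb chromosome
    standing in for the mapped chromosome (the full genome adds nothing to
    the statistics). ``causal_pos=None`` simulates a no-QTL null in which
    phenotypes are assigned at random with P(sterile) = 1/4.
    """

    chrom: str = "chr3"
    chrom_length: int = 10_000_000
    n_snps: int = 10_000
    causal_pos: int | None = 2_500_000
    n_f2: int = 600
    bulk_size: int = 50
    parent_pool_size: int = 20
    mean_depth: float = 19.0
    error_rate: float = 0.002
    recomb_cm_per_mb: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length < 1 or self.n_snps < 1:
            raise ConfigError("chrom_length and n_snps must be positive")
        if self.causal_pos is not None and not (
            1 <= self.causal_pos <= self.chrom_length
        ):
            raise ConfigError("causal_pos must lie inside the chromosome")
        if self.bulk_size < 1 or self.n_f2 < 1:
            raise ConfigError("bulk_size and n_f2 must be positive")
        if self.bulk_size > 0.25 * self.n_f2:
            raise ConfigError(
                "bulk_size exceeds the expected count of the rarer (sterile) "
                f"phenotypic class ({0.25 * self.n_f2:.0f} of n_f2={self.n_f2})"
            )
        if not 0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must be in [0, 0.5)")
        if self.mean_depth <= 0 or self.recomb_cm_per_mb < 0:
            raise ConfigError("mean_depth must be > 0 and recomb rate >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Named child generator; every stochastic step draws from its own."""
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class F2Record:
    """One F2 plant: phenotype plus AA/AB/BB genotypes per marker id."""

    plant_id: str
    phenotype: str
    genotypes: dict[str, str]


@dataclass
class F2Population:
    """An F2 population at a set of SNP markers on one chromosome.

    ``dosage[i, j]`` counts the P1 ("A") alleles (0/1/2) carried by plant i
    at marker j. ``causal_index`` is the column of the causal locus, or None
    for a no-QTL simulation.
    """

    chrom: str
    positions: np.ndarray  # 1-based bp, ascending
    ref_bases: np.ndarray  # P2 allele per marker
    alt_bases: np.ndarray  # P1 allele per marker
    dosage: np.ndarray  # (n_plants, n_markers) int8
    sterile: np.ndarray  # (n_plants,) bool
    causal_index: int | None
    config: SimConfig

    @property
    def n_plants(self) -> int:
        return self.dosage.shape[0]

    @property
    def marker_ids(self) -> list[str]:
        return [
            f"{r}{p}{a}"
            for r, p, a in zip(self.ref_bases, self.positions, self.alt_bases)
        ]

    def phenotype_labels(self) -> np.ndarray:
        return np.where(self.sterile, "sterile", "fertile")

    def records(self, marker_indices: Sequence[int] | None = None) -> Iterator[F2Record]:
        idx = range(len(self.positions)) if marker_indices is None else marker_indices
        ids = self.marker_ids
        labels = self.phenotype_labels()
        for i in range(self.n_plants):
            genos = {ids[j]: DOSAGE_TO_CODE[int(self.dosage[i, j])] for j in idx}
            yield F2Record(f"plant{i + 1}", str(labels[i]), genos)

    def to_f2_table(self, marker_indices: Sequence[int]) -> pd.DataFrame:
        """Fine-mapping TSV layout for a subset of markers."""
        ids = self.marker_ids
        data = {
            "plant_id": [f"plant{i + 1}" for i in range(self.n_plants)],
            "phenotype": self.phenotype_labels(),
        }
        code = np.array(["BB", "AB", "AA"])
        for j in marker_indices:
            data[ids[j]] = code[self.dosage[:, j]]
        return pd.DataFrame(data)


def _marker_positions(config: SimConfig) -> tuple[np.ndarray, int | None]:
    """Uniformly spaced SNP positions, with the causal locus inserted."""
    pos = np.unique(
        np.linspace(1, config.chrom_length, config.n_snps).round().astype(np.int64)
    )
    causal_index = None
    if config.causal_pos is not None:
        if config.causal_pos not in pos:
            pos = np.sort(np.append(pos, np.int64(config.causal_pos)))
        causal_index = int(np.searchsorted(pos, config.causal_pos))
    return pos, causal_index


def _draw_gametes(
    n: int, positions: np.ndarray, chrom_length: int, cm_per_mb: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, n_markers) int8 array of F1 gametes; 1 = P1-derived allele.

    Crossover counts are Poisson with mean equal to the chromosome's map
    length in Morgans (Haldane: no interference), breakpoints uniform.
    """
    morgans = cm_per_mb * (chrom_length / 1e6) / 100.0
    out = np.empty((n, positions.size), dtype=np.int8)
    k = rng.poisson(morgans, size=n)
    start = rng.integers(0, 2, size=n)
    for i in range(n):
        if k[i] == 0:
            out[i] = start[i]
        else:
            breaks = np.sort(rng.uniform(1.0, float(chrom_length), size=k[i]))
            out[i] = (start[i] + np.searchsorted(breaks, positions)) % 2
    return out


def _random_alleles(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return bases[ref], bases[alt]


def simulate_f2(config: SimConfig) -> F2Population:
    """Simulate an F2: each plant fuses two independent F1 gametes.

    Sterility is recessive and fully penetrant: a plant is sterile iff its
    causal-locus genotype is AA (homozygous for the P1 allele). With
    ``causal_pos=None`` phenotypes are instead random with P(sterile)=1/4.
    """
    config.validate()
    positions, causal_index = _marker_positions(config)
    rng = config.rng(1)
    g1 = _draw_gametes(
        config.n_f2, positions, config.chrom_length, config.recomb_cm_per_mb, rng
    )
    g2 = _draw_gametes(
        config.n_f2, positions, config.chrom_length, config.recomb_cm_per_mb, rng
    )
    dosage = (g1 + g2).astype(np.int8)
    if causal_index is None:
        sterile = config.rng(2).random(config.n_f2) < 0.25
    else:
        sterile = dosage[:, causal_index] == 2
    ref, alt = _random_alleles(positions.size, config.rng(3))
    return F2Population(
        config.chrom, positions, ref, alt, dosage, sterile, causal_index, config
    )


def simulate_testcross(config: SimConfig) -> F2Population:
    """Test cross: sterile P1 parent (aa) pollinated by the heterozygous F1.

    One gamete is always the P1 haplotype; the other is an F1 mosaic, so a
    recessive trait segregates sterile:fertile ≈ 1:1.
    """
    config.validate()
    positions, causal_index = _marker_positions(config)
    rng = config.rng(1)
    g1 = _draw_gametes(
        config.n_f2, positions, config.chrom_length, config.recomb_cm_per_mb, rng
    )
    dosage = (g1 + 1).astype(np.int8)  # the P1 gamete contributes one A everywhere
    if causal_index is None:
        sterile = config.rng(2).random(config.n_f2) < 0.5
    else:
        sterile = dosage[:, causal_index] == 2
    ref, alt = _random_alleles(positions.size, config.rng(3))
    return F2Population(
        config.chrom, positions, ref, alt, dosage, sterile, causal_index, config
    )


@dataclass(frozen=True)
class Bulks:
    """Index arrays of the phenotype-selected bulk members (disjoint)."""

    mf: np.ndarray
    ms: np.ndarray


def make_bulks(population: F2Population, config: SimConfig | None = None) -> Bulks:
    """Select the MS bulk from sterile plants and the MF bulk from fertile ones.

    Membership is a seeded random draw without replacement; an insufficient
    phenotypic class is a fatal configuration error.
    """
    config = config or population.config
    rng = config.rng(4)
    sterile_idx = np.flatnonzero(population.sterile)
    fertile_idx = np.flatnonzero(~population.sterile)
    for name, idx in (("sterile", sterile_idx), ("fertile", fertile_idx)):
        if idx.size < config.bulk_size:
            raise ConfigError(
                f"only {idx.size} {name} plants available; "
                f"bulk_size={config.bulk_size} required"
            )
    ms = rng.choice(sterile_idx, size=config.bulk_size, replace=False)
    mf = rng.choice(fertile_idx, size=config.bulk_size, replace=False)
    return Bulks(mf=np.sort(mf), ms=np.sort(ms))


def pool_alt_frequency(population: F2Population, members: np.ndarray) -> np.ndarray:
    """True P1-allele frequency per site: mean genotype dosage / 2."""
    return population.dosage[members].mean(axis=0) / 2.0


def simulate_pool_depths(
    alt_freq: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ref_depth, alt_depth) per site for one pool.

    Total depth is Poisson(mean_depth); each read samples the pool's true
    allele frequency and is miscalled (flipped to the other allele) with
    probability ``error_rate``.
    """
    alt_freq = np.asarray(alt_freq, dtype=float)
    total = rng.poisson(config.mean_depth, size=alt_freq.shape)
    p = alt_freq * (1 - config.error_rate) + (1 - alt_freq) * config.error_rate
    alt = rng.binomial(total, p)
    return total - alt, alt


def simulate_pools(
    population: F2Population, bulks: Bulks, config: SimConfig | None = None
) -> list[PoolSite]:
    """Sequence the four pools (P1, P2, MF, MS) into a PoolSite table.

    The inbred parents are fixed: the P1 pool's true ALT (mutant-allele)
    frequency is 1 at every site, the P2 pool's is 0; bulk frequencies are
    the mean genotype dosage of their member plants.
    """
    config = config or population.config
    rng = config.rng(5)
    n = population.positions.size
    freqs = {
        "P1": np.ones(n),
        "P2": np.zeros(n),
        "MF": pool_alt_frequency(population, bulks.mf),
        "MS": pool_alt_frequency(population, bulks.ms),
    }
    depths = {pool: simulate_pool_depths(freqs[pool], config, rng) for pool in POOLS}
    sites = []
    for j in range(n):
        site_depths = {
            pool: (int(depths[pool][0][j]), int(depths[pool][1][j])) for pool in POOLS
        }
        sites.append(
            PoolSite(
                population.chrom,
                int(population.positions[j]),
                str(population.ref_bases[j]),
                str(population.alt_bases[j]),
                site_depths,
            )
        )
    return sites


def simulate_null_sites(n_sites: int, config: SimConfig) -> list[PoolSite]:
    """A no-QTL calibration table whose sites are statistically independent.

    Each site draws its own MF and MS bulks of ``bulk_size`` plants from
    1:2:1 F2 genotype probabilities (so the bulk allele frequency is
    Binomial(2·bulk_size, 1/2)/(2·bulk_size), independently per site), then
    sequences all four pools exactly as :func:`simulate_pools` does. Use this
    for null-bound calibration checks, where site independence is assumed;
    a linked chromosome shares one bulk across sites and correlates them.
    """
    config.validate()
    rng = config.rng(6)
    two_n = 2 * config.bulk_size
    freqs = {
        "P1": np.ones(n_sites),
        "P2": np.zeros(n_sites),
        "MF": rng.binomial(two_n, 0.5, size=n_sites) / two_n,
        "MS": rng.binomial(two_n, 0.5, size=n_sites) / two_n,
    }
    depths = {pool: simulate_pool_depths(freqs[pool], config, rng) for pool in POOLS}
    ref, alt = _random_alleles(n_sites, config.rng(7))
    spacing = max(1, config.chrom_length // max(n_sites, 1))
    sites = []
    for j in range(n_sites):
        site_depths = {
            pool: (int(depths[pool][0][j]), int(depths[pool][1][j])) for pool in POOLS
        }
        sites.append(
            PoolSite(config.chrom, 1 + j * spacing, str(ref[j]), str(alt[j]), site_depths)
        )
    return sites


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

#: Default fine-mapping marker offsets (bp) relative to the causal locus,
#: chosen to bracket it at KASP-marker-like spacing.
DEFAULT_FINEMAP_OFFSETS = (-150_000, -60_000, -20_000, 15_000, 50_000, 110_000, 200_000)


def finemap_marker_indices(
    population: F2Population, offsets: Sequence[int] = DEFAULT_FINEMAP_OFFSETS
) -> list[int]:
    """Indices of the markers nearest causal_pos + offset (unique, sorted)."""
    config = population.config
    anchor = config.causal_pos if config.causal_pos is not None else config.chrom_length // 2
    targets = [
        min(max(anchor + off, 1), config.chrom_length) for off in offsets
    ]
    idx = sorted(
        {
            int(np.argmin(np.abs(population.positions - t)))
            for t in targets
        }
    )
    return idx


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete synthetic dataset: pool VCF, F2 table, truth JSON.

    The truth file records the causal position, seed and fine-mapping marker
    ids so downstream checks can score recovery without re-deriving them.
    Outputs are byte-identical for identical configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    population = simulate_f2(config)
    bulks = make_bulks(population, config)
    sites = simulate_pools(population, bulks, config)

    vcf_path = out_dir / "pools.vcf"
    write_pool_vcf(sites, vcf_path, contig_lengths={config.chrom: config.chrom_length})

    idx = finemap_marker_indices(population)
    f2_path = out_dir / "f2_genotypes.tsv"
    write_f2_table(population.to_f2_table(idx), f2_path)

    truth_path = out_dir / "truth.json"
    truth = {
        "chrom": config.chrom,
        "causal_pos": config.causal_pos,
        "seed": config.seed,
        "n_sites": len(sites),
        "finemap_markers": [population.marker_ids[j] for j in idx],
        "config": dataclasses.asdict(config),
    }
    atomic_write_text(truth_path, json.dumps(truth, indent=2) + "\n")
    log.info("fixture written to %s (%d sites)", out_dir, len(sites))
    return {"vcf": vcf_path, "f2": f2_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# Synthetic candidate gene (for effect-annotation fixtures)
# ---------------------------------------------------------------------------

def make_candidate_gene(
    seed: int = 0,
    chrom: str = "chr3",
    offset: int = 780_000,
    strand: str = "+",
    gene_id: str = "CandidateGene1",
) -> tuple[dict[str, str], GeneModel, tuple[str, int, str, str]]:
    """Build a synthetic 3-exon gene with a 1,995 bp CDS and a Tyr420 codon.

    Returns ``(genome, gene_model, variant)`` where the variant is the
    T→G substitution at codon 420 position 1 (TAT→GAT, Tyr→Asp), placed in
    the third exon. The CDS comprises 665 codons including the terminal
    stop, so the encoded protein is 664 residues. Synthetic stand-in for a
    real annotation: coordinates are arbitrary but internally consistent.
    """
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < 664:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in stops:
            codons.append(c)
    codons[419] = "TAT"  # codon 420, 1-based: tyrosine
    codons.append("TAA")
    cds_seq = "".join(codons)
    assert len(cds_seq) == 1995

    exon_cds_lengths = (600, 600, 795)
    intron_len = 250
    flank = 400
    cds_intervals: list[tuple[int, int]] = []
    plus_seq = []
    left_flank = "".join(rng.choice(list(bases), size=offset + flank - 1))
    plus_seq.append(left_flank)
    pos = offset + flank
    cds_cursor = 0
    intron = lambda: "GT" + "".join(rng.choice(list(bases), size=intron_len - 4)) + "AG"
    for i, ln in enumerate(exon_cds_lengths):
        start = pos
        plus_seq.append(cds_seq[cds_cursor : cds_cursor + ln])
        cds_cursor += ln
        pos += ln
        cds_intervals.append((start, pos - 1))
        if i < len(exon_cds_lengths) - 1:
            plus_seq.append(intron())
            pos += intron_len
    right_flank = "".join(rng.choice(list(bases), size=flank))
    plus_seq.append(right_flank)
    genome_plus = "".join(plus_seq)

    # codon 420, base 1 is CDS offset 419*3 = 1257 (0-based), inside exon 3.
    cds_off = 419 * 3
    exon3_start = cds_intervals[2][0]
    var_pos_plus = exon3_start + (cds_off - 1200)
    assert genome_plus[var_pos_plus - 1] == "T"

    if strand == "+":
        genome = {chrom: genome_plus}
        exons = tuple(cds_intervals)
        cds = tuple(cds_intervals)
        variant = (chrom, var_pos_plus, "T", "G")
    else:
        # Mirror the whole build: reverse-complement the chromosome so the
        # same transcript reads 5'→3' on the minus strand.
        from .io import revcomp

        L = len(genome_plus)
        genome = {chrom: revcomp(genome_plus)}
        flip = lambda s, e: (L - e + 1, L - s + 1)
        exons = tuple(sorted(flip(s, e) for s, e in cds_intervals))
        cds = tuple(sorted((flip(s, e) for s, e in cds_intervals), reverse=True))
        variant = (chrom, L - var_pos_plus + 1, "A", "C")
    gene = GeneModel(gene_id, chrom, strand, exons, cds)
    return genome, gene, variant
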