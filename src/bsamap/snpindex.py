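"""Per-site SNP-index, parental-consistency filtering and Δ(SNP-index).

The SNP-index of a pool at a site is the fraction of its reads carrying
the mutant-parent (P1) allele; with that orientation the sterile bulk's
index rises towards 1 near a recessive sterility locus while the fertile
bulk's expectation is 1/3 (fertile F2 plants are 2 Aa : 1 AA in
reference-allele terms, i.e. carry the mutant allele at frequency 1/3).
Δ(SNP-index) is the unsigned difference, largest minus smallest, so it
lies in [0, 1] and a one-sided upper confidence bound applies.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import PoolSite

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 8
DEFAULT_PARENT_PURITY = 0.9


def snp_index(ref_depth, alt_depth, p1_allele: str = "alt"):
    """Fraction of reads carrying the P1 (mutant-parent) allele.

    Accepts scalars or arrays; total depth must be positive (zero-depth
    sites are excluded upstream by :func:`filter_sites`).
    """
    ref_depth = np.asarray(ref_depth, dtype=float)
    alt_depth = np.asarray(alt_depth, dtype=float)
    total = ref_depth + alt_depth
    if np.any(total <= 0):
        raise ValueError("snp_index undefined at zero total depth")
    p1 = alt_depth if p1_allele == "alt" else ref_depth
    out = p1 / total
    return float(out) if out.ndim == 0 else out


def delta_snp_index(index_mf, index_ms, signed: bool = False):
    """Δ(SNP-index): largest minus smallest (or MS − MF when ``signed``)."""
    diff = np.asarray(index_ms, dtype=float) - np.asarray(index_mf, dtype=float)
    out = diff if signed else np.abs(diff)
    return float(out) if out.ndim == 0 else out


def p1_allele_of(site: PoolSite) -> str:
    """Orient a site: the P1 allele is the majority allele in the P1 pool."""
    r, a = site.depths["P1"]
    return "alt" if a > r else "ref"


def filter_sites(
    sites: Iterable[PoolSite],
    min_depth: int = DEFAULT_MIN_DEPTH,
    parent_purity: float = DEFAULT_PARENT_PURITY,
    stats: dict | None = None,
) -> list[PoolSite]:
    """Keep sites where every pool is covered and the parents are fixed.

    A site is retained when (i) each of the four pools has total depth >=
    ``min_depth`` and (ii) the parental pools are consistent: the P1 pool
    carries the P1 allele at fraction >= ``parent_purity`` and the P2 pool
    at fraction <= 1 − ``parent_purity`` — the same principle used to
    screen SNPs for genotyping marker design (P1 agrees with MS, P2 with
    MF at a true locus).
    """
    kept: list[PoolSite] = []
    n_depth = n_purity = 0
    for site in sites:
        if any(site.total_depth(pool) < min_depth for pool in site.depths):
            n_depth += 1
            continue
        p1 = p1_allele_of(site)
        f_p1 = snp_index(*site.depths["P1"], p1_allele=p1)
        f_p2 = snp_index(*site.depths["P2"], p1_allele=p1)
        if f_p1 < parent_purity or f_p2 > 1 - parent_purity:
            n_purity += 1
            continue
        kept.append(site)
    log.info(
        "filter_sites: kept %d, dropped %d (depth < %d), %d (parent purity < %.2f)",
        len(kept), n_depth, min_depth, n_purity, parent_purity,
    )
    if stats is not None:
        stats.update(
            {"n_kept": len(kept), "n_low_depth": n_depth, "n_impure_parent": n_purity}
        )
    return kept


def index_table(
    sites: Sequence[PoolSite],
    min_depth: int = DEFAULT_MIN_DEPTH,
    parent_purity: float = DEFAULT_PARENT_PURITY,
    signed: bool = False,
    stats: dict | None = None,
) -> pd.DataFrame:
    """Filter sites and tabulate per-site indices and Δ(SNP-index).

    Columns: chrom, pos, ref, alt, p1_allele, index_MF, index_MS,
    depth_MF, depth_MS, delta. Rows are in genomic order.
    """
    kept = filter_sites(sites, min_depth, parent_purity, stats=stats)
    rows = []
    for site in kept:
        p1 = p1_allele_of(site)
        i_mf = snp_index(*site.depths["MF"], p1_allele=p1)
        i_ms = snp_index(*site.depths["MS"], p1_allele=p1)
        rows.append(
            (
                site.chrom, site.pos, site.ref_allele, site.alt_allele, p1,
                i_mf, i_ms,
                site.total_depth("MF"), site.total_depth("MS"),
                delta_snp_index(i_mf, i_ms, signed=signed),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "p1_allele",
            "index_MF", "index_MS", "depth_MF", "depth_MS", "delta",
        ],
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
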