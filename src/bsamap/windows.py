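"""Sliding-window smoothing, simulated null confidence bounds, region calls.

Windows are 1 Mb wide and advance in 10 kb steps by default, matching
standard QTL-seq practice. The null distribution of Δ(SNP-index) at a
site depends on the read depths of the two bulks, so an upper confidence
bound is obtained by Monte-Carlo simulation conditioned on the observed
depth pair: per replicate each bulk's true allele frequency is the mean
dosage of ``bulk_size`` plants drawn from 1:2:1 F2 genotype
probabilities, read counts are binomial at the given depths, and Δ is
recomputed; the bound is the upper q-quantile. Per-site bounds are
averaged within a window and compared to the window's mean Δ; maximal
runs of significant windows are merged into candidate regions whose
boundaries are SNP positions (position resolution, finer than the window
grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 10_000
DEFAULT_MIN_SNPS = 3
DEFAULT_N_SIM = 10_000
DEFAULT_Q = 0.99


def make_windows(
    chrom_length: int, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> np.ndarray:
    """1-based inclusive (start, end) pairs: starts 1, 1+step, … ≤ length.

    The final windows are truncated at the chromosome end.
    """
    if not (1 <= step <= window):
        raise ConfigError("require window >= step >= 1")
    starts = np.arange(1, chrom_length + 1, step, dtype=np.int64)
    ends = np.minimum(starts + window - 1, chrom_length)
    return np.column_stack([starts, ends])


class NullBoundSimulator:
    """Depth-conditioned Monte-Carlo null bounds for Δ(SNP-index), memoized.

    One simulator holds ``n_sim`` replicate bulk allele frequencies (drawn
    once: the mean dosage/2 of ``bulk_size`` plants from 1:2:1 genotype
    probabilities is Binomial(2·bulk_size, 1/2)/(2·bulk_size)) and lazily
    materializes per-depth binomial read draws, so bounds for the many
    depth pairs of a genome scan share the replicate ensemble. Results are
    cached by integer (depth_MF, depth_MS) and are reproducible for a given
    seed regardless of query order.
    """

    def __init__(
        self,
        bulk_size: int,
        n_sim: int = DEFAULT_N_SIM,
        q: float = DEFAULT_Q,
        seed: int = 0,
    ):
        if n_sim < 1000:
            raise ConfigError("n_sim must be >= 1000 for a stable 99% quantile")
        if not 0 < q < 1:
            raise ConfigError("q must be in (0, 1)")
        self.bulk_size = int(bulk_size)
        self.n_sim = int(n_sim)
        self.q = float(q)
        self.seed = int(seed)
        two_n = 2 * self.bulk_size
        self._freq = {
            side: np.random.default_rng([self.seed, k]).binomial(
                two_n, 0.5, size=self.n_sim
            )
            / two_n
            for k, side in enumerate(("MF", "MS"))
        }
        self._index_cache: dict[tuple[str, int], np.ndarray] = {}
        self._bound_cache: dict[tuple[int, int], float] = {}

    def _indices(self, side: str, depth: int) -> np.ndarray:
        key = (side, depth)
        if key not in self._index_cache:
            # Per-(side, depth) child generator keeps results order-independent.
            rng = np.random.default_rng(
                [self.seed, 2 + ("MF", "MS").index(side), depth]
            )
            reads = rng.binomial(depth, self._freq[side])
            self._index_cache[key] = reads / depth
        return self._index_cache[key]

    def bound(self, depth_mf: int, depth_ms: int) -> float:
        """Upper q-quantile of Δ(SNP-index) under no linkage at these depths."""
        depth_mf, depth_ms = int(round(depth_mf)), int(round(depth_ms))
        if depth_mf < 1 or depth_ms < 1:
            raise ConfigError("depths must be >= 1")
        key = (depth_mf, depth_ms)
        if key not in self._bound_cache:
            delta = np.abs(
                self._indices("MF", depth_mf) - self._indices("MS", depth_ms)
            )
            self._bound_cache[key] = float(np.quantile(delta, self.q))
        return self._bound_cache[key]

    def bounds(self, depth_mf: np.ndarray, depth_ms: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bound` over parallel depth arrays."""
        depth_mf = np.asarray(depth_mf, dtype=np.int64)
        depth_ms = np.asarray(depth_ms, dtype=np.int64)
        pairs = np.column_stack([depth_mf, depth_ms])
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        vals = np.array([self.bound(d1, d2) for d1, d2 in uniq])
        return vals[inverse]


@dataclass(frozen=True)
class WindowStat:
    """One genomic window's averaged statistics."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_delta: float  # NaN when n_snps < min_snps
    mean_ci99: float
    significant: bool


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of significant windows, bounded by its first/last SNP."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_delta: float

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def size_kb(self) -> int:
        """Physical span in Kb, truncated toward zero as in printed reports."""
        return self.size // 1000


def window_average(
    records: pd.DataFrame,
    windows: np.ndarray,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> pd.DataFrame:
    """Average per-site delta (and ci99 when present) in each window.

    ``records`` must be a single-chromosome index table sorted by ``pos``;
    windows with fewer than ``min_snps`` sites have NaN means and are never
    significant. Returns one row per window: chrom, start, end, n_snps,
    mean_delta[, mean_ci99, significant].
    """
    if len(records) and records["pos"].is_monotonic_increasing is False:
        records = records.sort_values("pos", kind="stable")
    chroms = records["chrom"].unique() if len(records) else []
    if len(chroms) > 1:
        raise ConfigError("window_average operates on a single chromosome")
    chrom = chroms[0] if len(chroms) else ""

    pos = records["pos"].to_numpy() if len(records) else np.empty(0, dtype=np.int64)
    delta = records["delta"].to_numpy() if len(records) else np.empty(0)
    has_ci = "ci99" in records.columns
    cum_delta = np.concatenate([[0.0], np.cumsum(delta)])
    if has_ci:
        cum_ci = np.concatenate([[0.0], np.cumsum(records["ci99"].to_numpy())])

    lo = np.searchsorted(pos, windows[:, 0], side="left")
    hi = np.searchsorted(pos, windows[:, 1], side="right")
    n = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_delta = np.where(n > 0, (cum_delta[hi] - cum_delta[lo]) / np.maximum(n, 1), np.nan)
    mean_delta = np.where(n >= min_snps, mean_delta, np.nan)
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "start": windows[:, 0],
            "end": windows[:, 1],
            "n_snps": n,
            "mean_delta": mean_delta,
        }
    )
    if has_ci:
        mean_ci = np.where(n > 0, (cum_ci[hi] - cum_ci[lo]) / np.maximum(n, 1), np.nan)
        mean_ci = np.where(n >= min_snps, mean_ci, np.nan)
        out["mean_ci99"] = mean_ci
        out["significant"] = (out["mean_delta"] > out["mean_ci99"]).fillna(False)
    return out


def attach_null_bounds(
    records: pd.DataFrame, simulator: NullBoundSimulator
) -> pd.DataFrame:
    """Add a per-site ``ci99`` column (the depth-conditioned null bound)."""
    records = records.copy()
    records["ci99"] = simulator.bounds(
        records["depth_MF"].to_numpy(), records["depth_MS"].to_numpy()
    )
    return records


def call_regions(stats: pd.DataFrame, records: pd.DataFrame) -> list[CandidateRegion]:
    """Merge overlapping/adjacent significant windows into candidate regions.

    Region boundaries are the positions of the first and last SNP inside
    the merged window span (position resolution); ``size = end − start``.
    Merged spans that contain no SNP are dropped.
    """
    if "significant" not in stats.columns:
        raise ConfigError("stats must carry a 'significant' column (attach bounds first)")
    sig = stats[stats["significant"]].sort_values("start")
    if sig.empty:
        return []
    pos = np.sort(records["pos"].to_numpy())
    regions: list[CandidateRegion] = []
    cur_start = cur_end = None
    cur_n = 0
    cur_peak = -np.inf

    def flush():
        lo = np.searchsorted(pos, cur_start, side="left")
        hi = np.searchsorted(pos, cur_end, side="right")
        if hi - lo < 2:
            return  # fewer than two SNPs: no physical span to report
        regions.append(
            CandidateRegion(
                str(sig.iloc[0]["chrom"]),
                int(pos[lo]),
                int(pos[hi - 1]),
                cur_n,
                float(cur_peak),
            )
        )

    for row in sig.itertuples(index=False):
        if cur_start is None:
            cur_start, cur_end, cur_n, cur_peak = row.start, row.end, 1, row.mean_delta
        elif row.start <= cur_end + 1:
            cur_end = max(cur_end, row.end)
            cur_n += 1
            cur_peak = max(cur_peak, row.mean_delta)
        else:
            flush()
            cur_start, cur_end, cur_n, cur_peak = row.start, row.end, 1, row.mean_delta
    flush()
    return regions


def top_region(regions: list[CandidateRegion]) -> CandidateRegion | None:
    """The candidate region with the highest window mean Δ(SNP-index)."""
    return max(regions, key=lambda r: r.peak_delta, default=None)


def regions_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.size, r.size_kb, r.n_windows, r.peak_delta)
            for r in regions
        ],
        columns=["chrom", "start", "end", "size_bp", "size_kb", "n_windows", "peak_delta"],
    )
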