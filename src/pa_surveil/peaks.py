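"""Kernel-density clustering of adenylation sites into peaks.

Sites retained by the filters are smoothed with a Gaussian kernel (default
bandwidth 5 bp — poly(A) 3' ends are near-single-nucleotide features) and
maximal contiguous regions of above-threshold density become peak clusters,
per contig and strand.  Each cluster reports its mode (the member position
with the highest raw count in the focal sample; ties break to the most 5'
position in transcript orientation), the central 95% interval of the read
positions, the narrow-peak flag (95% interval narrower than 10 bp), and a
windowed raw-read sum over mode +/- 2 per sample.

The default calling threshold equals the density a lone minimum-depth
(5-read) site would produce at a distance of two bandwidths — isolated
retained sites always form their own cluster, and background never does.

The 95% interval is the tightest central interval: its low end is the
smallest position with strictly more than 2.5% of reads at or below it, and
its high end the smallest position with at least 97.5% at or below it.  For
n reads expanded to a sorted position multiset v (1-based), that is
``[v[floor(0.025 n) + 1], v[ceil(0.975 n)]]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sites import PASiteTable

DEFAULT_BANDWIDTH = 5.0
NARROW_WIDTH = 10  # a peak is narrow iff its 95% interval is < 10 bp wide
MODE_WINDOW = 2  # window sums cover mode +/- 2 (five positions)


def default_threshold(bandwidth: float = DEFAULT_BANDWIDTH, min_reads: int = 5) -> float:
    """Density of a lone `min_reads`-read site evaluated two bandwidths away."""
    return min_reads * norm.pdf(2.0) / bandwidth


@dataclass
class PeakCluster:
    contig: str
    strand: str
    positions: np.ndarray  # member site positions (sorted ascending)
    counts: pd.DataFrame  # rows = member positions, columns = raw_<sample>
    mode: int
    interval95: tuple[int, int]
    width95: int
    narrow: bool
    totals: dict[str, int]
    window_sums: dict[str, int]

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.strand}:{self.mode}"


def density_profile(
    table: PASiteTable, sample: str, bandwidth: float = DEFAULT_BANDWIDTH
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Gaussian kernel density of retained read counts, per (contig, strand).

    density(x) = sum over sites of count x N((x - pos)/bw)/bw, truncated to
    zero beyond four bandwidths of any site.  Returns integer grids with
    their density values.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    retained = table.retained(sample)
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    reach = math.ceil(4 * bandwidth)
    offsets = np.arange(-reach, reach + 1)
    kernel = norm.pdf(offsets / bandwidth) / bandwidth
    for (contig, strand), sub in retained.groupby(level=["contig", "strand"], sort=True):
        pos = sub.index.get_level_values("position").to_numpy()
        cnt = sub[f"raw_{sample}"].to_numpy()
        lo, hi = int(pos.min()) - reach, int(pos.max()) + reach
        grid = np.arange(lo, hi + 1)
        dens = np.zeros(grid.size)
        for p, c in zip(pos, cnt):
            i = p - lo - reach
            dens[i : i + kernel.size] += c * kernel
        out[(contig, strand)] = (grid, dens)
    return out


def _quantile_bounds(positions: np.ndarray, counts: np.ndarray) -> tuple[int, int]:
    """Central-95% bounds of a weighted discrete position distribution
    (integer-exact; see module docstring for the convention)."""
    cum = np.cumsum(counts)
    n = int(cum[-1])
    lo_idx = int(np.searchsorted(cum * 1000, 25 * n, side="right"))
    hi_idx = int(np.searchsorted(cum * 1000, 975 * n, side="left"))
    return int(positions[lo_idx]), int(positions[hi_idx])


def cluster_stats(
    member_df: pd.DataFrame,
    table: PASiteTable,
    contig: str,
    strand: str,
    sample: str,
) -> PeakCluster:
    """Compute mode, 95% interval, narrow flag and windowed sums for the
    member sites of one cluster."""
    if member_df.empty:
        raise ValueError("empty cluster")
    positions = member_df.index.get_level_values("position").to_numpy()
    order = np.argsort(positions)
    positions = positions[order]
    member_df = member_df.iloc[order]
    cnt = member_df[f"raw_{sample}"].to_numpy()
    best = cnt.max()
    tied = positions[cnt == best]
    mode = int(tied.min() if strand == "+" else tied.max())
    lo, hi = _quantile_bounds(positions, cnt)
    width = hi - lo + 1
    totals = {s: int(member_df[f"raw_{s}"].sum()) for s in table.samples}
    window_sums = {
        s: table.directed_counts(contig, strand, mode - MODE_WINDOW, mode + MODE_WINDOW, s)
        for s in table.samples
    }
    return PeakCluster(
        contig=contig,
        strand=strand,
        positions=positions,
        counts=member_df[[f"raw_{s}" for s in table.samples]],
        mode=mode,
        interval95=(lo, hi),
        width95=width,
        narrow=width < NARROW_WIDTH,
        totals=totals,
        window_sums=window_sums,
    )


def call_clusters(
    table: PASiteTable,
    sample: str,
    bandwidth: float = DEFAULT_BANDWIDTH,
    threshold: float | None = None,
) -> list[PeakCluster]:
    """Call peaks on the focal sample's retained sites.

    Clusters are maximal contiguous runs of grid positions whose density is
    at or above the threshold; member sites on different strands never
    merge, and every retained site belongs to exactly one cluster (a
    retained site's own density always exceeds the default threshold).
    """
    if threshold is None:
        threshold = default_threshold(bandwidth)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    retained = table.retained(sample)
    profiles = density_profile(table, sample, bandwidth)
    clusters: list[PeakCluster] = []
    for (contig, strand), (grid, dens) in sorted(profiles.items()):
        above = dens >= threshold
        # run starts/ends of the boolean mask
        edges = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(above.size)
        sub = retained.loc[(contig, strand)]
        pos = sub.index.to_numpy()
        for s, e in zip(starts, ends):
            lo, hi = int(grid[s]), int(grid[e - 1])
            sel = (pos >= lo) & (pos <= hi)
            if not sel.any():
                continue
            member_index = pd.MultiIndex.from_arrays(
                [
                    np.repeat(contig, sel.sum()),
                    np.repeat(strand, sel.sum()),
                    pos[sel],
                ],
                names=["contig", "strand", "position"],
            )
            member_df = table.df.loc[member_index]
            clusters.append(cluster_stats(member_df, table, contig, strand, sample))
    return clusters
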