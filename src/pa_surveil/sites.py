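"""Per-nucleotide adenylation-site table: tallying, filters, normalisation.

Accepted mapping hits are tallied into a strand-aware table keyed by
(contig, strand, position) with one raw-count column per sample.  Three
annotations are layered on top:

* ``below_min_<sample>`` — the site has fewer than ``min_reads`` (default 5)
  mapped reads in that sample and is ignored by undirected analyses there;
  directed feature-anchored queries may bypass the flag.
* ``templated_a`` — the 20 genomic bases immediately downstream of the site
  in transcript orientation contain a run of >= 6 adenosines or >= 15
  adenosines in total: the apparent poly(A) tail can be explained by
  oligo-dT priming on genomically encoded A's, so the site is excluded from
  all downstream peak and differential computations.
* ``rpm_<sample>`` — raw counts scaled to reads per million mapped reads of
  the same sequencing run (the only normalisation applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapper import MappedHit
from .simdata import ToyGenome


@dataclass
class PASiteTable:
    """Wide table of adenylation sites.

    ``df`` is indexed by (contig, strand, position) and carries
    ``raw_<sample>`` count columns plus flag/rpm columns added by the
    filter and normalisation steps.
    """

    df: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def raw(self, sample: str) -> pd.Series:
        return self.df[f"raw_{sample}"]

    def retained(self, sample: str) -> pd.DataFrame:
        """Sites surviving both filters for `sample`."""
        mask = ~self.df[f"below_min_{sample}"] & ~self.df["templated_a"]
        return self.df[mask]

    def directed_counts(
        self, contig: str, strand: str, lo: int, hi: int, sample: str
    ) -> int:
        """Raw reads on (contig, strand) at positions in [lo, hi], bypassing
        the minimum-read flag (a directed query)."""
        sub = self.df.loc[
            (self.df.index.get_level_values("contig") == contig)
            & (self.df.index.get_level_values("strand") == strand)
        ]
        pos = sub.index.get_level_values("position")
        return int(sub.loc[(pos >= lo) & (pos <= hi), f"raw_{sample}"].sum())


def tally(hits: list[MappedHit], samples: list[str] | None = None) -> PASiteTable:
    """Count hits per (contig, strand, position) and sample."""
    if samples is None:
        samples = sorted({h.sample for h in hits})
    counts: dict[tuple[str, str, int], dict[str, int]] = {}
    for h in hits:
        key = (h.contig, h.strand, h.pa_position)
        row = counts.setdefault(key, {})
        row[h.sample] = row.get(h.sample, 0) + 1
    index = pd.MultiIndex.from_tuples(
        sorted(counts), names=["contig", "strand", "position"]
    )
    data = {
        f"raw_{s}": [counts[k].get(s, 0) for k in index] for s in samples
    }
    df = pd.DataFrame(data, index=index, dtype=np.int64)
    return PASiteTable(df, samples)


def apply_min_reads(table: PASiteTable, min_reads: int = 5) -> PASiteTable:
    """Flag, per sample, sites with fewer than `min_reads` mapped reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    for s in table.samples:
        table.df[f"below_min_{s}"] = table.df[f"raw_{s}"] < min_reads
    return table


def normalize_rpm(table: PASiteTable, mapped_totals: dict[str, int]) -> PASiteTable:
    """Populate rpm columns: raw x 10^6 / mapped reads of the same run."""
    for s in table.samples:
        if s not in mapped_totals:
            raise KeyError(f"no mapped total for sample {s!r}")
        if mapped_totals[s] <= 0:
            raise ValueError(f"mapped total for {s!r} must be positive")
        table.df[f"rpm_{s}"] = table.df[f"raw_{s}"] * 1e6 / mapped_totals[s]
    return table


def templated_a_window(
    genome: ToyGenome, contig: str, strand: str, position: int, window: int = 20
) -> str:
    """The up-to-`window` genomic bases immediately downstream of a site in
    transcript orientation, read on the transcript strand."""
    seq = genome.contigs[contig]
    if strand == "+":
        return seq[position + 1 : position + 1 + window]
    lo = max(position - window, 0)
    return genome.fetch(contig, lo, position, "-")


def is_templated_a(window_seq: str, run_len: int = 6, window: int = 20, window_hits: int = 15) -> bool:
    """Apply the internal-priming rule to a downstream window sequence.

    Flags when the window contains >= `run_len` consecutive A's or
    >= `window_hits` A's in total.  Windows truncated at a contig end are
    judged on the available bases with both thresholds scaled
    proportionally (rounded up); an empty window never flags.
    """
    n = len(window_seq)
    if n == 0:
        return False
    if n < window:
        run_len = math.ceil(run_len * n / window)
        window_hits = math.ceil(window_hits * n / window)
    longest = run = 0
    total = 0
    for c in window_seq:
        if c == "A":
            total += 1
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    return longest >= run_len or total >= window_hits


def filter_templated_a(
    table: PASiteTable,
    genome: ToyGenome,
    run_len: int = 6,
    window: int = 20,
    window_hits: int = 15,
) -> PASiteTable:
    """Flag sites whose downstream genomic window triggers the
    internal-priming (templated adenosine) rule."""
    flags = []
    for contig, strand, position in table.df.index:
        w = templated_a_window(genome, contig, strand, position, window)
        flags.append(is_templated_a(w, run_len, window, window_hits))
    table.df["templated_a"] = flags
    return table
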