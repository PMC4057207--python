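"""Mismatch-tolerant paired-end mapping of oriented PA-seq reads.

A seed-and-verify exact mapper adequate for toy genomes: a k-mer index gives
exact seed hits, pigeonhole seeding guarantees completeness for up to two
mismatches, and every accepted pair becomes a single-nucleotide adenylation
"hit" at the genomic base adjacent to the trimmed TTT tag of the 3' read.

Mapping rules: the 3' read may differ from the genome by at most two
mismatches (counted on the templated portion only; no indels), the 5' mate
must align on the opposite genomic strand, inward-facing, on the same contig
within a maximum span; pairs with no candidate placement are unmapped, pairs
with ten or more are discarded, pairs with two to nine are assigned to one
placement uniformly at random with a seeded generator, and a chosen
placement overlapping an annotated repeat is discarded.

Because the 3' read is the reverse complement of the transcript's 3' end,
the transcript strand is the opposite of the 3' read's alignment strand:
a 3' read aligned to the minus genomic strand reports a plus-strand
adenylation site at the alignment's last base, and vice versa.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .readprep import OrientedReadPair
from .simdata import ToyGenome, revcomp

UNMAPPED = "unmapped"
DISCARD_MULTIMAPPED = "multimapped"
DISCARD_REPEAT = "repeat"


@dataclass(frozen=True)
class Placement:
    """Alignment of a single read: genome[start:start+length] matches the
    read (strand '+') or its reverse complement (strand '-') within the
    mismatch budget."""

    contig: str
    start: int
    strand: str
    length: int
    mismatches: int


@dataclass
class MappedHit:
    sample: str
    contig: str
    strand: str  # transcript strand of the adenylated RNA
    pa_position: int  # genomic coordinate of the 3'-terminal templated base
    n_candidate_positions: int
    five_prime_mate_interval: tuple[str, int, int, str]
    name: str = ""


@dataclass
class MapParams:
    max_mismatches_3p: int = 2
    max_mismatches_5p: int = 2
    max_span: int = 1000
    max_candidates: int = 10  # >= this many placements -> discarded


class GenomeIndex:
    """Exact k-mer position index over the plus strand of every contig.

    Minus-strand occurrences are found by querying the reverse complement,
    so a palindromic k-mer yields one record per (position, strand), never a
    double count.
    """

    def __init__(self, genome: ToyGenome, k: int = 12):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.genome = genome
        self.arrays = {
            name: np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, seq in genome.contigs.items()
        }
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((name, i))
        self._index = dict(self._index)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Plus-strand occurrences of `kmer`."""
        return self._index.get(kmer, [])

    def find_kmer(self, kmer: str) -> list[tuple[str, int, str]]:
        """All occurrences of `kmer` on both strands, as (contig, plus-strand
        start of the occupied interval, strand)."""
        out = [(c, p, "+") for c, p in self.lookup(kmer)]
        out += [(c, p, "-") for c, p in self.lookup(revcomp(kmer))]
        return out

    def _verify(self, contig: str, start: int, query: np.ndarray, max_mm: int) -> int:
        arr = self.arrays[contig]
        L = len(query)
        if start < 0 or start + L > len(arr):
            return -1
        mm = int(np.count_nonzero(arr[start : start + L] != query))
        return mm if mm <= max_mm else -1

    def candidates(self, seq: str, max_mm: int = 2) -> list[Placement]:
        """Every placement of `seq` on either strand with <= max_mm
        mismatches.

        Pigeonhole seeding: three disjoint k-mer seeds from the read's first
        3k bases — with at most two mismatches at least one seed is exact.
        Reads shorter than 3k fall back to a full scan of the genome.
        """
        L = len(seq)
        out: list[Placement] = []
        seen: set[tuple[str, int, str]] = set()
        for strand in ("+", "-"):
            query = seq if strand == "+" else revcomp(seq)
            qarr = np.frombuffer(query.encode(), dtype=np.uint8)
            if L >= 3 * self.k:
                starts: set[tuple[str, int]] = set()
                for off in (0, self.k, 2 * self.k):
                    for contig, pos in self.lookup(query[off : off + self.k]):
                        starts.add((contig, pos - off))
                for contig, s in starts:
                    mm = self._verify(contig, s, qarr, max_mm)
                    if mm >= 0 and (contig, s, strand) not in seen:
                        seen.add((contig, s, strand))
                        out.append(Placement(contig, s, strand, L, mm))
            else:
                for contig, arr in self.arrays.items():
                    if len(arr) < L:
                        continue
                    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
                    mms = np.count_nonzero(windows != qarr, axis=1)
                    for s in np.flatnonzero(mms <= max_mm):
                        key = (contig, int(s), strand)
                        if key not in seen:
                            seen.add(key)
                            out.append(
                                Placement(contig, int(s), strand, L, int(mms[s]))
                            )
        return out


def build_index(genome: ToyGenome, k: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, k)


def build_repeat_trees(repeats: list[tuple[str, int, int]]):
    """Repeat intervals as per-contig interval trees for overlap queries."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for contig, start, end in repeats:
        trees[contig].addi(start, end)
    return dict(trees)


def _compatible_five_prime(
    p3: Placement, placements5: list[Placement], max_span: int
) -> Placement | None:
    """Best inward-facing 5'-mate placement for a 3'-read placement.

    The 5' mate aligns on the opposite genomic strand of the 3' read and
    sits 5'-ward in transcript orientation; span is measured over the outer
    fragment ends.  Returns the tightest compatible placement (smallest
    span, then leftmost), or None.
    """
    best: tuple[int, int, Placement] | None = None
    for p5 in placements5:
        if p5.contig != p3.contig or p5.strand == p3.strand:
            continue
        if p3.strand == "-":  # transcript on plus strand; 5' mate left of 3' mate
            span = (p3.start + p3.length) - p5.start
            ok = p5.start <= p3.start and span <= max_span and span >= p3.length
        else:  # transcript on minus strand; 5' mate right of 3' mate
            span = (p5.start + p5.length) - p3.start
            ok = p5.start >= p3.start and span <= max_span and span >= p3.length
        if ok:
            key = (span, p5.start, p5)
            if best is None or key[:2] < best[:2]:
                best = key
    return best[2] if best else None


def map_pair(
    pair: OrientedReadPair,
    index: GenomeIndex,
    params: MapParams,
    rng: np.random.Generator,
    repeat_trees=None,
    _cache: dict | None = None,
) -> MappedHit | str:
    """Map one oriented pair; returns a MappedHit or a reason code."""
    if _cache is None:
        _cache = {}
    key3 = ("3", pair.three_prime_seq)
    if key3 not in _cache:
        _cache[key3] = index.candidates(pair.three_prime_seq, params.max_mismatches_3p)
    key5 = ("5", pair.five_prime_seq)
    if key5 not in _cache:
        _cache[key5] = index.candidates(pair.five_prime_seq, params.max_mismatches_5p)
    cands3, cands5 = _cache[key3], _cache[key5]

    valid: list[tuple[Placement, Placement]] = []
    for p3 in cands3:
        p5 = _compatible_five_prime(p3, cands5, params.max_span)
        if p5 is not None:
            valid.append((p3, p5))
    if not valid:
        return UNMAPPED
    if len(valid) >= params.max_candidates:
        return DISCARD_MULTIMAPPED
    if len(valid) == 1:
        p3, p5 = valid[0]
    else:
        p3, p5 = valid[int(rng.integers(len(valid)))]
    if repeat_trees is not None:
        tree = repeat_trees.get(p3.contig)
        if tree is not None and tree.overlap(p3.start, p3.start + p3.length):
            return DISCARD_REPEAT
    if p3.strand == "-":
        strand, pa = "+", p3.start + p3.length - 1
    else:
        strand, pa = "-", p3.start
    return MappedHit(
        sample=pair.sample,
        contig=p3.contig,
        strand=strand,
        pa_position=pa,
        n_candidate_positions=len(valid),
        five_prime_mate_interval=(p5.contig, p5.start, p5.start + p5.length, p5.strand),
        name=pair.name,
    )


def map_reads(
    pairs: list[OrientedReadPair],
    index: GenomeIndex,
    params: MapParams | None = None,
    seed: int = 0,
    repeats: list[tuple[str, int, int]] | None = None,
) -> tuple[list[MappedHit], dict[str, int]]:
    """Map a batch of oriented pairs with one seeded RNG and shared caches.

    Returns accepted hits and a tally of rejection reasons.
    """
    params = params or MapParams()
    rng = np.random.default_rng(seed)
    repeat_trees = build_repeat_trees(repeats) if repeats else None
    cache: dict = {}
    hits: list[MappedHit] = []
    rejections: dict[str, int] = {}
    for pair in pairs:
        out = map_pair(pair, index, params, rng, repeat_trees, cache)
        if isinstance(out, MappedHit):
            hits.append(out)
        else:
            rejections[out] = rejections.get(out, 0) + 1
    return hits, rejections


def percent_mapped(raw: int, mapped: int) -> float:
    """Percentage of raw reads mapped, rounded to one decimal place."""
    if raw == 0:
        import warnings

        warnings.warn("raw read count is zero; reporting 0%", stacklevel=2)
        return 0.0
    return round(100.0 * mapped / raw, 1)


def mapping_summary(raw_counts: dict[str, int], hits: list[MappedHit]):
    """Per-sample bookkeeping: raw reads, mapped reads, percent mapped and
    distinct genomic (contig, strand, position) adenylation sites."""
    import pandas as pd

    mapped: dict[str, int] = {s: 0 for s in raw_counts}
    positions: dict[str, set] = {s: set() for s in raw_counts}
    for h in hits:
        mapped[h.sample] = mapped.get(h.sample, 0) + 1
        positions.setdefault(h.sample, set()).add((h.contig, h.strand, h.pa_position))
    rows = []
    for sample, raw in raw_counts.items():
        rows.append(
            {
                "sample": sample,
                "raw_reads": raw,
                "mapped_reads": mapped.get(sample, 0),
                "percent_mapped": percent_mapped(raw, mapped.get(sample, 0)),
                "total_genomic_positions": len(positions.get(sample, ())),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
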