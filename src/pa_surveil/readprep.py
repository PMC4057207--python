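"""Demultiplexing and TTT-tag orientation of raw PA-seq read pairs.

Pairs are assigned to samples by a perfect match of the first five bases of
read 1 to a registered barcode (no mismatch rescue), the barcode is trimmed,
and the mate that opens with exactly three T's is designated the 3'-end
read (the tag is the remnant of the oligo-dT/deoxyU/TTTVN primer after USER
cleavage).  Exactly three T's are trimmed; any fourth leading T is templated
(the complement of a 3'-terminal A is excluded by the V anchor, but
sequencing error can produce one) and is left for the mapper to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

TAG = "TTT"
MIN_TEMPLATED_LENGTH = 8  # post-trim reads shorter than this cannot map usefully


@dataclass
class OrientedReadPair:
    sample: str
    name: str
    three_prime_seq: str  # TTT tag removed
    five_prime_seq: str
    tag_ok: bool = True


@dataclass
class DemuxResult:
    assigned: dict[str, list]  # sample -> list of pairs
    unassigned: list
    counts: dict[str, int]


def demultiplex(pairs: Iterable, barcodes: dict[str, str]) -> DemuxResult:
    """Split a raw pair stream by exact 5-nt barcode match on read 1.

    `pairs` yields objects with ``name``, ``read1`` and ``read2`` attributes
    (e.g. :class:`~pa_surveil.simdata.ReadPair`).  Assigned pairs have the
    barcode trimmed from read 1.  Raises on duplicate barcodes.
    """
    codes = list(barcodes.values())
    if any(len(b) != 5 for b in codes):
        raise ValueError("barcodes must be exactly 5 nt")
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate barcodes in configuration")
    lookup = {b: s for s, b in barcodes.items()}
    assigned: dict[str, list] = {s: [] for s in barcodes}
    unassigned: list = []
    for pair in pairs:
        sample = lookup.get(pair.read1[:5])
        if sample is None:
            unassigned.append(pair)
        else:
            trimmed = type(pair)(pair.name, pair.read1[5:], pair.read2)
            assigned[sample].append(trimmed)
    counts = {s: len(v) for s, v in assigned.items()}
    counts["unassigned"] = len(unassigned)
    return DemuxResult(assigned, unassigned, counts)


REJECT_NO_TAG = "no_tag"
REJECT_AMBIGUOUS_TAG = "ambiguous_tag"
REJECT_TOO_SHORT = "too_short"


def orient_pair(
    sample: str, name: str, mate1: str, mate2: str, min_length: int = MIN_TEMPLATED_LENGTH
) -> OrientedReadPair | str:
    """Designate the TTT-initiated mate as the 3' read and trim its tag.

    Returns an :class:`OrientedReadPair`, or a rejection reason string when
    both mates, or neither mate, open with the tag, or when the templated
    remainder is too short to map.
    """
    t1, t2 = mate1.startswith(TAG), mate2.startswith(TAG)
    if t1 and t2:
        return REJECT_AMBIGUOUS_TAG
    if not (t1 or t2):
        return REJECT_NO_TAG
    three, five = (mate1, mate2) if t1 else (mate2, mate1)
    three = three[len(TAG):]
    if len(three) < min_length:
        return REJECT_TOO_SHORT
    return OrientedReadPair(sample, name, three, five)


def orient_pairs(
    sample: str, pairs: Iterable, min_length: int = MIN_TEMPLATED_LENGTH
) -> tuple[list[OrientedReadPair], dict[str, int]]:
    """Orient every pair of a demultiplexed sample; tally rejection reasons."""
    oriented: list[OrientedReadPair] = []
    rejected: dict[str, int] = {}
    for pair in pairs:
        out = orient_pair(sample, pair.name, pair.read1, pair.read2, min_length)
        if isinstance(out, OrientedReadPair):
            oriented.append(out)
        else:
            rejected[out] = rejected.get(out, 0) + 1
    return oriented, rejected


def iter_fastq_pairs(r1_path, r2_path) -> Iterator:
    """Yield ReadPair-like records from two parallel FASTQ files."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    from .simdata import ReadPair

    with open(r1_path) as f1, open(r2_path) as f2:
        for (t1, s1, _q1), (_t2, s2, _q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            yield ReadPair(t1.split()[0], s1, s2)
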