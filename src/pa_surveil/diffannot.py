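"""Knockdown-versus-control differential adenylation and feature anchoring.

Covers the comparative analyses downstream of peak calling: per-gene modal
poly(A) sites near annotated 3' ends with replicate R^2; the log2 KD/control
ratio histogram for the null mRNA complement; categorisation of peaks as
annotated mRNA poly(A) sites, repeat elements, or neither; ranking of
"neither" peaks by KD/control ratio of windowed mode sums; the directed
miRNA 5'-leader scan at predicted Drosha cleavage sites; positional
adenylation profiles around feature 3' ends (pooled across identical
copies); and a 5'-mate containment QC for distinguishing bona fide feature
processing from read-through transcription.

Ratios are reported raw (no pseudocount, no significance testing — ranking
by ratio only); a control count of zero is reported as not detected ("N.D.").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapper import MappedHit
from .peaks import MODE_WINDOW, PeakCluster
from .simdata import Gene, Hairpin, SnoRNA
from .sites import PASiteTable

ND = "N.D."
CATEGORY_REFSEQ = "refseq_pa"
CATEGORY_REPEAT = "repeat"
CATEGORY_NEITHER = "neither"


@dataclass
class DifferentialRecord:
    feature_id: str
    contig: str
    strand: str
    mode: int  # 0-based internally; reports add 1
    kd_reads: int
    ctrl_reads: int
    ratio: float | None  # None when ctrl_reads == 0 (N.D.)
    log2_ratio: float | None
    category: str
    note: str = ""


@dataclass
class LeaderCall:
    mirna: str
    cluster: str
    contig: str
    strand: str
    drosha_site: int
    kd_reads: int
    ctrl_reads: int
    ratio: float | None
    modal_position: int | None  # position of max KD reads within the window


def differential_ratio(kd_reads: int, ctrl_reads: int) -> float | None:
    """KD/control ratio; None (not detected in control) when ctrl is zero."""
    if ctrl_reads == 0:
        return None
    return kd_reads / ctrl_reads


def refseq_modal_sites(
    table: PASiteTable,
    genes: list[Gene],
    kd_sample: str,
    ctrl_sample: str,
    window: int = 50,
    min_modal_reads: int = 5,
) -> pd.DataFrame:
    """Per-gene modal poly(A) position within +/-`window` of the annotated
    3' end, with per-sample counts.

    Candidates are retained sites on the gene's strand; the modal position
    carries the maximum pooled raw count (ties break to the position closest
    to the annotated end, then most 5'); a gene is reported only when the
    modal raw count reaches `min_modal_reads` in the focal (KD) sample.
    """
    rows = []
    for gene in genes:
        end3 = gene.end3
        sub = table.df[
            (table.df.index.get_level_values("contig") == gene.contig)
            & (table.df.index.get_level_values("strand") == gene.strand)
            & ~table.df["templated_a"]
        ]
        pos = sub.index.get_level_values("position")
        sub = sub[(pos >= end3 - window) & (pos <= end3 + window)]
        if sub.empty:
            continue
        pooled = sub[f"raw_{kd_sample}"] + sub[f"raw_{ctrl_sample}"]
        best = pooled.max()
        tied = sub[pooled == best].index.get_level_values("position").to_numpy()
        dist = np.abs(tied - end3)
        tied = tied[dist == dist.min()]
        modal = int(tied.min() if gene.strand == "+" else tied.max())
        row = sub.xs(modal, level="position").iloc[0]
        if row[f"raw_{kd_sample}"] < min_modal_reads:
            continue
        rows.append(
            {
                "gene": gene.name,
                "contig": gene.contig,
                "strand": gene.strand,
                "modal_position": modal,
                "kd_reads": int(row[f"raw_{kd_sample}"]),
                "ctrl_reads": int(row[f"raw_{ctrl_sample}"]),
                "kd_rpm": float(row.get(f"rpm_{kd_sample}", np.nan)),
                "ctrl_rpm": float(row.get(f"rpm_{ctrl_sample}", np.nan)),
            }
        )
    return pd.DataFrame(rows)


def scatter_r2(a: np.ndarray, b: np.ndarray, log: bool = True) -> tuple[float, bool]:
    """Coefficient of determination between two modal-site count vectors.

    R^2 is the squared Pearson correlation of log10 values across entries
    positive in both samples (zeros excluded).  Returns (R^2,
    positive_slope); an anti-correlated pair still has R^2 near 1, so the
    sign is reported alongside.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    keep = (a > 0) & (b > 0)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 shared positive entries")
    if log:
        a, b = np.log10(a), np.log10(b)
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r, r > 0


def log2_bin_label(value: float) -> str:
    """Histogram bin label for a log2 ratio.

    The centre bin (-0.2, +0.2] is labelled "0"; successive bins are 0.4
    wide and labelled by the outer edge relative to zero (+0.6, +1.0, ...;
    symmetric negative labels).
    """
    if -0.2 <= value <= 0.2:  # centre bin, symmetric about zero
        return "0"
    k = math.ceil((abs(value) - 0.2) / 0.4)
    edge = 0.2 + 0.4 * k
    sign = "+" if value > 0 else "-"
    return f"{sign}{edge:.1f}"


def log2_histogram(log2_ratios: list[float | None]) -> tuple[pd.Series, float, int]:
    """Bin log2 KD/control ratios into the fixed-width labelled bins.

    Returns (bin counts indexed by label, fraction with |log2| < 1,
    number of undefined ratios excluded).
    """
    defined = [v for v in log2_ratios if v is not None and np.isfinite(v)]
    undefined = len(log2_ratios) - len(defined)
    labels = [log2_bin_label(v) for v in defined]
    counts = pd.Series(labels).value_counts()

    def edge_key(lab: str) -> float:
        return 0.0 if lab == "0" else float(lab)

    counts = counts.sort_index(key=lambda idx: idx.map(edge_key))
    frac_within = (
        float(np.mean([abs(v) < 1 for v in defined])) if defined else float("nan")
    )
    return counts, frac_within, undefined


def categorize_peaks(
    clusters: list[PeakCluster],
    genes: list[Gene],
    repeats: list[tuple[str, int, int]],
    window: int = 50,
) -> list[str]:
    """Assign each cluster a category by precedence: annotated mRNA poly(A)
    site (mode within +/-`window` of a gene 3' end on the matching strand),
    then repeat (mode inside a repeat interval), then neither."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for contig, start, end in repeats:
        trees.setdefault(contig, IntervalTree()).addi(start, end)
    gene_ends: dict[tuple[str, str], list[int]] = {}
    for g in genes:
        gene_ends.setdefault((g.contig, g.strand), []).append(g.end3)
    out = []
    for cl in clusters:
        ends = gene_ends.get((cl.contig, cl.strand), [])
        if any(abs(cl.mode - e) <= window for e in ends):
            out.append(CATEGORY_REFSEQ)
        elif cl.contig in trees and trees[cl.contig].overlap(cl.mode, cl.mode + 1):
            out.append(CATEGORY_REPEAT)
        else:
            out.append(CATEGORY_NEITHER)
    return out


def rank_neither(
    clusters: list[PeakCluster],
    categories: list[str],
    kd_sample: str,
    ctrl_sample: str,
    include_nd: bool = True,
) -> list[DifferentialRecord]:
    """Rank "neither"-category peaks by KD/control ratio of their windowed
    (mode +/- 2) raw-read sums, highest first; control-zero peaks rank above
    every finite ratio (or are dropped when `include_nd` is false)."""
    records = []
    for cl, cat in zip(clusters, categories):
        if cat != CATEGORY_NEITHER:
            continue
        kd = cl.window_sums[kd_sample]
        ctrl = cl.window_sums[ctrl_sample]
        ratio = differential_ratio(kd, ctrl)
        if ratio is None and not include_nd:
            continue
        records.append(
            DifferentialRecord(
                feature_id=cl.name,
                contig=cl.contig,
                strand=cl.strand,
                mode=cl.mode,
                kd_reads=kd,
                ctrl_reads=ctrl,
                ratio=ratio,
                log2_ratio=math.log2(ratio) if ratio else None,
                category=CATEGORY_NEITHER,
            )
        )
    records.sort(
        key=lambda r: (math.inf if r.ratio is None else r.ratio, r.kd_reads),
        reverse=True,
    )
    return records


def mirna_leader_scan(
    table: PASiteTable,
    hairpins: list[Hairpin],
    kd_sample: str,
    ctrl_sample: str,
    tol: int = MODE_WINDOW,
    include_all: bool = False,
) -> list[LeaderCall]:
    """Directed query of adenylation at predicted Drosha cleavage sites.

    For every annotated hairpin the Drosha site is the base immediately 5'
    of the hairpin in transcript orientation; reads are raw sums over
    drosha +/- tol on the transcript strand, deliberately bypassing the
    minimum-read flag.  Calls with zero reads in both conditions are
    suppressed unless `include_all`.
    """
    calls = []
    for hp in hairpins:
        d = hp.drosha_site
        if d < 0:
            continue  # hairpin at contig edge: no leader to interrogate
        kd = table.directed_counts(hp.contig, hp.strand, d - tol, d + tol, kd_sample)
        ctrl = table.directed_counts(hp.contig, hp.strand, d - tol, d + tol, ctrl_sample)
        if kd == 0 and ctrl == 0 and not include_all:
            continue
        sub = table.df[
            (table.df.index.get_level_values("contig") == hp.contig)
            & (table.df.index.get_level_values("strand") == hp.strand)
        ]
        pos = sub.index.get_level_values("position")
        win = sub[(pos >= d - tol) & (pos <= d + tol)]
        modal = None
        if not win.empty and win[f"raw_{kd_sample}"].max() > 0:
            kd_counts = win[f"raw_{kd_sample}"]
            tied = win[kd_counts == kd_counts.max()].index.get_level_values("position")
            modal = int(tied.min() if hp.strand == "+" else tied.max())
        calls.append(
            LeaderCall(
                mirna=hp.name,
                cluster=hp.cluster,
                contig=hp.contig,
                strand=hp.strand,
                drosha_site=d,
                kd_reads=kd,
                ctrl_reads=ctrl,
                ratio=differential_ratio(kd, ctrl),
                modal_position=modal,
            )
        )
    return calls


def positional_profile(
    table: PASiteTable,
    features: list[SnoRNA] | list[Gene],
    samples: list[str],
    offset_range: tuple[int, int] = (-10, 10),
) -> pd.DataFrame:
    """Adenylation counts by offset from feature 3' ends, pooled over the
    given features (e.g. the identical tandem copies of a snoRNA).

    Offset 0 is the annotated 3'-end base; negative offsets lie inside the
    feature (over-trimmed species), positive offsets beyond it.  On the
    minus strand, genomic position end3 - k maps to offset +k.
    """
    lo, hi = offset_range
    offsets = np.arange(lo, hi + 1)
    data = {s: np.zeros(offsets.size, dtype=np.int64) for s in samples}
    for feat in features:
        end3 = feat.end3
        sign = 1 if feat.strand == "+" else -1
        for k, off in enumerate(offsets):
            p = end3 + sign * off
            try:
                row = table.df.loc[(feat.contig, feat.strand, int(p))]
            except KeyError:
                continue
            if bool(row.get("templated_a", False)):
                continue
            for s in samples:
                data[s][k] += int(row[f"raw_{s}"])
    df = pd.DataFrame(data, index=pd.Index(offsets, name="offset"))
    return df


def cumulative_offset_ratio(
    profile: pd.DataFrame, kd_sample: str, ctrl_sample: str, lo: int, hi: int
) -> float | None:
    """KD/control ratio of reads summed over an offset sub-range [lo, hi]."""
    kd = int(profile.loc[lo:hi, kd_sample].sum())
    ctrl = int(profile.loc[lo:hi, ctrl_sample].sum())
    return differential_ratio(kd, ctrl)


def five_prime_mate_qc(
    hits: list[MappedHit], contig: str, start: int, end: int
) -> float | None:
    """Fraction of hits (with adenylation site inside [start, end)) whose 5'
    mate aligns fully inside the feature interval; None when no hits."""
    inside = total = 0
    for h in hits:
        if h.contig != contig or not (start <= h.pa_position < end):
            continue
        total += 1
        mc, ms, me, _strand = h.five_prime_mate_interval
        if mc == contig and ms >= start and me <= end:
            inside += 1
    if total == 0:
        return None
    return inside / total
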