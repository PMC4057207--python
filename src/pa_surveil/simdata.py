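"""Toy genome construction and PA-seq read simulation with planted truth.

The simulator stands in for the real sequencing experiment: it builds a small
two-contig genome carrying every feature class the pipeline must handle —
protein-coding genes with canonical poly(A) sites, an rRNA unit with named
5'ETS processing sites (A', A0, 18S junction), identical tandem snoRNA
copies (multimapping), pri-miRNA hairpins inside host transcripts, a
many-copy repeat family, and deliberate internal-priming traps sitting on
genomically encoded A-runs — and then emits paired-end reads with the PA-seq
library structure: read 1 opens with a 5-nt sample barcode, and the 3'-end
mate opens with a TTT tag immediately followed by the complement of the
transcript's 3'-terminal templated residue.

Site abundances are relative weights; a sample's reads are multinomially
distributed over sites in proportion to weight x (fold change, in the
knockdown), so each library has exactly ``n_read_pairs`` pairs.  Because both
conditions are sampled to the same depth, the expected KD/control count
ratio at a site is the planted fold divided by the ratio of total weights
(close to, but not exactly, the fold); :func:`expected_counts` gives the
exact expectations for use as an oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CATEGORIES = ("mRNA_PA", "ETS_A0", "snoRNA_offset", "mirna_leader", "internal_priming_trap")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class SizingError(ValueError):
    """Requested feature layout does not fit in the configured genome length."""


@dataclass
class ToyGenome:
    """Contig name -> plus-strand nucleotide string (A/C/G/T only)."""

    contigs: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """0-based half-open slice; minus strand returns the reverse complement."""
        seq = self.contigs[contig][start:end]
        return revcomp(seq) if strand == "-" else seq

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")


@dataclass
class Gene:
    contig: str
    strand: str
    start: int  # 0-based, half-open [start, end)
    end: int
    name: str

    @property
    def end3(self) -> int:
        """Genomic position of the last transcribed base (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class SnoRNA:
    contig: str
    strand: str
    start: int
    end: int
    copy_group: str
    name: str

    @property
    def end3(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Hairpin:
    contig: str
    strand: str
    start: int
    end: int
    name: str
    cluster: str

    @property
    def drosha_site(self) -> int:
        """Genomic position of the base immediately 5' of the hairpin in
        transcript orientation — the 3'-terminal base of the Drosha-released
        5' leader."""
        return self.start - 1 if self.strand == "+" else self.end


@dataclass
class RRNASites:
    """Named 5'ETS processing-site coordinates on the (plus-strand) rRNA unit.

    Each coordinate is the genomic position of the 3'-terminal base of the
    fragment that terminates at that site.
    """

    contig: str
    a_prime: int
    a0: int
    site1: int  # 18S junction

    def as_dict(self) -> dict[str, int]:
        return {"A_prime": self.a_prime, "A0": self.a0, "site1": self.site1}


@dataclass
class AnnotationSet:
    genes: list[Gene] = field(default_factory=list)
    repeats: list[tuple[str, int, int]] = field(default_factory=list)
    snornas: list[SnoRNA] = field(default_factory=list)
    hairpins: list[Hairpin] = field(default_factory=list)
    rrna_sites: RRNASites | None = None


@dataclass
class TruthRecord:
    site_id: str
    contig: str
    strand: str
    position: int  # genomic coordinate of the true 3'-terminal templated base
    category: str
    abundance_control: float
    fold_change_kd: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")
        if self.fold_change_kd <= 0:
            raise ValueError("fold_change_kd must be > 0")
        if self.abundance_control < 0:
            raise ValueError("abundance_control must be >= 0")


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    def by_category(self, category: str) -> list[TruthRecord]:
        return [r for r in self.records if r.category == category]


@dataclass
class SimConfig:
    """Sequencing-run parameters for the simulator.

    Defaults emulate the study conditions: two libraries (control and
    Mtr4-knockdown) of 2x10^5 pairs each, 50-nt reads, a 100-180 bp
    size-selected fragment window, exact 5-nt barcodes, a 3-nt T tag, and a
    low uniform substitution-error rate.
    """

    n_read_pairs: int = 200_000
    read_length: int = 50
    fragment_range: tuple[int, int] = (100, 180)
    barcodes: dict[str, str] = field(
        default_factory=lambda: {"control": "AGCTC", "kd": "CGATG"}
    )
    error_rate: float = 0.001
    tag: str = "TTT"
    seed: int = 0
    jitter_prob: float = 0.1  # probability that a read's 3' end sits at site +/- 1
    quality_char: str = "I"

    def __post_init__(self) -> None:
        codes = list(self.barcodes.values())
        if any(len(b) != 5 for b in codes):
            raise ValueError("barcodes must be exactly 5 nt")
        if len(set(codes)) != len(codes):
            raise ValueError("barcodes must be pairwise distinct")
        lo, hi = self.fragment_range
        if not (100 <= lo <= hi <= 1000):
            raise ValueError("fragment range must lie within [100, 1000]")
        if self.read_length > lo:
            raise ValueError("read length must not exceed the minimum fragment size")


@dataclass
class GenomeLayout:
    """Feature counts, sizes and planted effect sizes for the toy genome.

    The planted fold changes are the study conditions the pipeline must
    recover: a null mRNA complement (fold 1), snoRNA -1..-3 over-trimmed
    species at fold 9, the 5'ETS A0 fragment at fold 8, and miRNA 5' leaders
    at fold 60.
    """

    chr1_length: int = 26_000
    chr2_length: int = 14_000
    spacer: int = 150
    # protein-coding genes (null differential complement)
    n_genes: int = 30
    gene_length: int = 400
    gene_abundance_range: tuple[float, float] = (50.0, 2000.0)
    # unannotated PA sites: true 3' ends far from any annotated gene end
    n_orphans: int = 3
    orphan_length: int = 250
    orphan_abundance: float = 300.0
    # internal-priming traps
    n_traps: int = 2
    trap_abundance: float = 50.0
    trap_run: int = 8
    # repeat family (drives the >=10-candidate discard rule)
    repeat_copies: int = 12
    repeat_unit: int = 250
    # rRNA unit and 5'ETS processing sites (offsets within the unit)
    rrna_length: int = 2500
    rrna_a_prime: int = 300
    rrna_a0: int = 1000
    rrna_site1: int = 1800
    a0_abundance: float = 30.0
    a0_fold: float = 8.0
    # identical tandem snoRNA copies
    snorna_copies: int = 4
    snorna_length: int = 214
    snorna_end_abundance: float = 200.0
    snorna_offset_abundance: float = 15.0  # each of offsets -1, -2, -3
    snorna_offset_fold: float = 9.0
    # miRNA hairpins inside host transcripts
    hairpin_length: int = 60
    leader_abundance: float = 5.0
    leader_fold: float = 60.0
    host_abundance: float = 500.0


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n)


def _forbid(seq: np.ndarray, rng: np.random.Generator, lo: int, hi: int, base: bytes) -> None:
    """Replace occurrences of `base` in seq[lo:hi] with a random other base."""
    lo, hi = max(lo, 0), min(hi, len(seq))
    others = [b for b in (b"A", b"C", b"G", b"T") if b != base]
    idx = np.flatnonzero(seq[lo:hi] == base) + lo
    if idx.size:
        seq[idx] = rng.choice(np.array(others, dtype="S1"), size=idx.size)


def _constrain_site(seq: np.ndarray, rng: np.random.Generator, pos: int, strand: str) -> None:
    """Force the transcript-strand bases at [site-1 .. site+21] to be non-A.

    Keeps the VN primer anchor honest (the 3'-terminal residue is never A,
    even when a read's end is jittered by one base) and guarantees the
    downstream 20-nt window of a true site never triggers the templated-A
    internal-priming rule.
    """
    if strand == "+":
        _forbid(seq, rng, pos - 1, pos + 22, b"A")
    else:
        # non-A on the minus strand == non-T on the stored plus strand
        _forbid(seq, rng, pos - 21, pos + 2, b"T")


def build_toy_genome(
    layout: GenomeLayout | None = None, seed: int = 0
) -> tuple[ToyGenome, AnnotationSet, TruthTable]:
    """Construct the toy genome, its annotations and the planted truth table.

    Deterministic: the same (layout, seed) always yields byte-identical
    sequences.  Raises :class:`SizingError` when the requested features do
    not fit in the configured contig lengths.
    """
    layout = layout or GenomeLayout()
    rng = np.random.default_rng(seed)
    ann = AnnotationSet()
    truth: list[TruthRecord] = []

    # ---- chr1: genes, orphan PA sites, traps, repeat family ----
    chr1 = _random_seq(rng, layout.chr1_length)
    cursor = layout.spacer

    def advance(n: int, contig_len: int) -> int:
        nonlocal cursor
        start = cursor
        cursor += n + layout.spacer
        if cursor > contig_len:
            raise SizingError(
                f"layout requires more than the configured contig length ({contig_len} bp)"
            )
        return start

    lo_ab, hi_ab = layout.gene_abundance_range
    for i in range(layout.n_genes):
        start = advance(layout.gene_length, layout.chr1_length)
        strand = "+" if i % 2 == 0 else "-"
        gene = Gene("chr1", strand, start, start + layout.gene_length, f"gene{i:02d}")
        ann.genes.append(gene)
        _constrain_site(chr1, rng, gene.end3, strand)
        abundance = float(np.exp(rng.uniform(np.log(lo_ab), np.log(hi_ab))))
        truth.append(
            TruthRecord(gene.name, "chr1", strand, gene.end3, "mRNA_PA", abundance, 1.0)
        )

    for i in range(layout.n_orphans):
        start = advance(layout.orphan_length, layout.chr1_length)
        pos = start + layout.orphan_length - 1
        _constrain_site(chr1, rng, pos, "+")
        truth.append(
            TruthRecord(
                f"orphan{i}", "chr1", "+", pos, "mRNA_PA", layout.orphan_abundance, 1.0
            )
        )

    for i in range(layout.n_traps):
        start = advance(60 + layout.trap_run, layout.chr1_length)
        pos = start + 59  # apparent 3' end; the A-run begins at pos+1
        _constrain_site(chr1, rng, pos, "+")
        chr1[pos + 1 : pos + 1 + layout.trap_run] = np.frombuffer(b"A", dtype="S1")
        truth.append(
            TruthRecord(
                f"trap{i}",
                "chr1",
                "+",
                pos,
                "internal_priming_trap",
                layout.trap_abundance,
                1.0,
            )
        )

    if layout.repeat_copies:
        unit = _random_seq(rng, layout.repeat_unit)
        block_start = advance(
            layout.repeat_copies * layout.repeat_unit, layout.chr1_length
        )
        for c in range(layout.repeat_copies):
            s = block_start + c * layout.repeat_unit
            chr1[s : s + layout.repeat_unit] = unit
        ann.repeats.append(
            ("chr1", block_start, block_start + layout.repeat_copies * layout.repeat_unit)
        )

    # ---- chr2: rRNA unit, tandem snoRNA copies, miRNA host transcripts ----
    chr2 = _random_seq(rng, layout.chr2_length)
    cursor = layout.spacer

    r0 = advance(layout.rrna_length, layout.chr2_length)
    ann.rrna_sites = RRNASites(
        "chr2",
        a_prime=r0 + layout.rrna_a_prime,
        a0=r0 + layout.rrna_a0,
        site1=r0 + layout.rrna_site1,
    )
    _constrain_site(chr2, rng, ann.rrna_sites.a0, "+")
    truth.append(
        TruthRecord(
            "ets_a0",
            "chr2",
            "+",
            ann.rrna_sites.a0,
            "ETS_A0",
            layout.a0_abundance,
            layout.a0_fold,
        )
    )

    sno_template = _random_seq(rng, layout.snorna_length)
    # constrain the template's 3'-end neighbourhood once so all copies agree
    _forbid(sno_template, rng, layout.snorna_length - 5, layout.snorna_length, b"A")
    sno_spacer = 40
    sno_block = advance(
        layout.snorna_copies * (layout.snorna_length + sno_spacer), layout.chr2_length
    )
    for c in range(layout.snorna_copies):
        s = sno_block + c * (layout.snorna_length + sno_spacer)
        e = s + layout.snorna_length
        chr2[s:e] = sno_template
        _forbid(chr2, rng, e, e + 22, b"A")  # downstream window of the 3'-end site
        ann.snornas.append(SnoRNA("chr2", "+", s, e, "U3B", f"U3B.{c + 1}"))
    sno1 = ann.snornas[0]
    truth.append(
        TruthRecord(
            "u3_end",
            "chr2",
            "+",
            sno1.end3,
            "snoRNA_offset",
            layout.snorna_end_abundance,
            1.0,
        )
    )
    for off in (1, 2, 3):
        truth.append(
            TruthRecord(
                f"u3_minus{off}",
                "chr2",
                "+",
                sno1.end3 - off,
                "snoRNA_offset",
                layout.snorna_offset_abundance,
                layout.snorna_offset_fold,
            )
        )

    # host 1 (minus strand) with a two-hairpin cluster; leader planted on hairpin A
    host1_len = 1600
    h1 = advance(host1_len, layout.chr2_length)
    host1 = Gene("chr2", "-", h1, h1 + host1_len, "hostA")
    ann.genes.append(host1)
    _constrain_site(chr2, rng, host1.end3, "-")
    truth.append(
        TruthRecord(
            "hostA", "chr2", "-", host1.end3, "mRNA_PA", layout.host_abundance, 1.0
        )
    )
    hA_start = h1 + 600
    hpA = Hairpin("chr2", "-", hA_start, hA_start + layout.hairpin_length, "mirA", "clusterA")
    hB_start = h1 + 350
    hpB = Hairpin("chr2", "-", hB_start, hB_start + layout.hairpin_length, "mirB", "clusterA")
    ann.hairpins += [hpA, hpB]
    _constrain_site(chr2, rng, hpA.drosha_site, "-")
    truth.append(
        TruthRecord(
            "leader_mirA",
            "chr2",
            "-",
            hpA.drosha_site,
            "mirna_leader",
            layout.leader_abundance,
            layout.leader_fold,
        )
    )

    # host 2 (plus strand) with a lone hairpin and a planted leader
    host2_len = 800
    h2 = advance(host2_len, layout.chr2_length)
    host2 = Gene("chr2", "+", h2, h2 + host2_len, "hostB")
    ann.genes.append(host2)
    _constrain_site(chr2, rng, host2.end3, "+")
    truth.append(
        TruthRecord(
            "hostB", "chr2", "+", host2.end3, "mRNA_PA", layout.host_abundance, 1.0
        )
    )
    hC_start = h2 + 400
    hpC = Hairpin("chr2", "+", hC_start, hC_start + layout.hairpin_length, "mirC", "clusterB")
    ann.hairpins.append(hpC)
    _constrain_site(chr2, rng, hpC.drosha_site, "+")
    truth.append(
        TruthRecord(
            "leader_mirC",
            "chr2",
            "+",
            hpC.drosha_site,
            "mirna_leader",
            layout.leader_abundance,
            layout.leader_fold,
        )
    )

    genome = ToyGenome(
        {"chr1": chr1.tobytes().decode(), "chr2": chr2.tobytes().decode()}
    )
    return genome, ann, TruthTable(truth)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_CONDITION_STREAM = {"control": 0, "kd": 1}


@dataclass
class ReadPair:
    name: str
    read1: str
    read2: str


def site_weights(truth: TruthTable, condition: str) -> np.ndarray:
    if condition not in _CONDITION_STREAM:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_STREAM)}")
    w = np.array(
        [
            r.abundance_control * (r.fold_change_kd if condition == "kd" else 1.0)
            for r in truth.records
        ]
    )
    return w


def expected_counts(truth: TruthTable, cfg: SimConfig, condition: str) -> dict[str, float]:
    """Exact multinomial expectation of the read count at each truth site."""
    w = site_weights(truth, condition)
    probs = w / w.sum()
    return {
        r.site_id: float(cfg.n_read_pairs * p) for r, p in zip(truth.records, probs)
    }


def expected_window_counts(
    genome: ToyGenome,
    truth: TruthTable,
    cfg: SimConfig,
    condition: str,
    contig: str,
    strand: str,
    lo: int,
    hi: int,
) -> float:
    """Expected number of reads whose 3' end lands in [lo, hi] on (contig,
    strand), accounting for the +/-1 end jitter (a jitter step onto an
    adenosine or off the contig reverts to the planted site, mirroring the
    simulator)."""
    expect = expected_counts(truth, cfg, condition)
    total = 0.0
    for rec in truth.records:
        if rec.contig != contig or rec.strand != strand:
            continue
        seq = genome.contigs[rec.contig]
        probs = {rec.position: 1.0 - cfg.jitter_prob}
        stay = 0.0
        for d in (-1, 1):
            q = rec.position + d
            base = None
            if 0 <= q < len(seq):
                base = seq[q] if strand == "+" else seq[q].translate(COMPLEMENT)
            if base is None or base == "A":
                stay += cfg.jitter_prob / 2
            else:
                probs[q] = probs.get(q, 0.0) + cfg.jitter_prob / 2
        probs[rec.position] += stay
        total += expect[rec.site_id] * sum(
            p for q, p in probs.items() if lo <= q <= hi
        )
    return total


def _apply_errors(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(arr), size=min(n_err, len(arr)), replace=False)
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    for p in pos:
        choices = bases[bases != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_paseq_reads(
    genome: ToyGenome,
    truth: TruthTable,
    cfg: SimConfig,
    condition: str,
) -> list[ReadPair]:
    """Simulate one sample's paired-end PA-seq library.

    Every pair derives from a truth site: the 3'-end mate is
    ``TTT + reverse-complement of the template ending at the site`` (so the
    base after the tag is the complement of the 3'-terminal residue), the
    5' mate reads inward from the other end of a size-selected fragment, and
    read 1 of the pair (chosen at random between the two mates) is prefixed
    with the sample barcode.  Internal-priming-trap sites produce reads by
    the same mechanism — their apparent 3' end simply abuts a genomic A-run.
    Deterministic for fixed (genome, truth, cfg, condition).
    """
    if condition not in cfg.barcodes:
        raise ValueError(f"no barcode registered for sample {condition!r}")
    rng = np.random.default_rng([cfg.seed, _CONDITION_STREAM[condition]])
    barcode = cfg.barcodes[condition]
    rl = cfg.read_length
    tmpl_len = rl - len(cfg.tag)
    fmin, fmax = cfg.fragment_range

    w = site_weights(truth, condition)
    counts = rng.multinomial(cfg.n_read_pairs, w / w.sum())

    pairs: list[ReadPair] = []
    for rec, n in zip(truth.records, counts):
        if n == 0:
            continue
        contig = genome.contigs[rec.contig]
        clen = len(contig)
        jit = rng.choice(
            [0, -1, 1], size=n, p=[1 - cfg.jitter_prob, cfg.jitter_prob / 2, cfg.jitter_prob / 2]
        )
        frags = rng.integers(fmin, fmax + 1, size=n)
        first_is_3p = rng.random(n) < 0.5
        nerr1 = rng.binomial(rl + len(barcode), cfg.error_rate, size=n)
        nerr2 = rng.binomial(rl, cfg.error_rate, size=n)
        for i in range(n):
            q = rec.position + int(jit[i])
            # never jitter onto an A (the VN anchor forbids a terminal A) or
            # off the contig
            if q < 0 or q >= clen:
                q = rec.position
            base = contig[q] if rec.strand == "+" else contig[q].translate(COMPLEMENT)
            if base == "A":
                q = rec.position
            F = int(frags[i])
            if rec.strand == "+":
                if q - F + 1 < 0 or q - tmpl_len + 1 < 0:
                    continue  # fragment does not fit; skip (bounded by layout design)
                seq3 = cfg.tag + revcomp(contig[q - tmpl_len + 1 : q + 1])
                g5 = q - F + 1
                seq5 = contig[g5 : g5 + rl]
            else:
                if q + F > clen or q + tmpl_len > clen:
                    continue
                seq3 = cfg.tag + contig[q : q + tmpl_len]
                g5 = q + F - 1
                seq5 = revcomp(contig[g5 - rl + 1 : g5 + 1])
            name = f"{condition}:{rec.site_id}:{i}"
            if first_is_3p[i]:
                r1, r2 = barcode + seq3, seq5
            else:
                r1, r2 = barcode + seq5, seq3
            r1 = _apply_errors(r1, int(nerr1[i]), rng)
            r2 = _apply_errors(r2, int(nerr2[i]), rng)
            pairs.append(ReadPair(name, r1, r2))
    return pairs
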