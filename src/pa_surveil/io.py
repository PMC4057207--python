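"""On-disk formats: FASTA/FASTQ, BED, GFF3, and the pipeline's TSV tables.

Coordinates are 0-based half-open internally and in BED; GFF3 output is
1-based inclusive, converted at this boundary.  Human-facing report tables
(differential records, leader calls) echo 1-based coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .simdata import AnnotationSet, ReadPair, ToyGenome, TruthTable


def write_fasta(genome: ToyGenome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> ToyGenome:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return ToyGenome({name: str(fa[name][:]) for name in fa.keys()})


def write_fastq(pairs: list[ReadPair], r1_path, r2_path, quality_char: str = "I") -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.read1}\n+\n{quality_char * len(p.read1)}\n")
            f2.write(f"@{p.name}/2\n{p.read2}\n+\n{quality_char * len(p.read2)}\n")


def write_annotations(ann: AnnotationSet, outdir) -> None:
    outdir = Path(outdir)
    with open(outdir / "genes.bed", "w") as fh:
        for g in ann.genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
    with open(outdir / "repeats.bed", "w") as fh:
        for contig, start, end in ann.repeats:
            fh.write(f"{contig}\t{start}\t{end}\trepeat\t0\t+\n")
    with open(outdir / "snorna.bed", "w") as fh:
        for s in ann.snornas:
            fh.write(
                f"{s.contig}\t{s.start}\t{s.end}\t{s.name}:{s.copy_group}\t0\t{s.strand}\n"
            )
    with open(outdir / "hairpins.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        for hp in ann.hairpins:
            fh.write(
                f"{hp.contig}\tpa_surveil\tpre_miRNA\t{hp.start + 1}\t{hp.end}\t.\t"
                f"{hp.strand}\t.\tID={hp.name};cluster={hp.cluster}\n"
            )
    if ann.rrna_sites is not None:
        with open(outdir / "rrna_sites.tsv", "w") as fh:
            fh.write("site\tcontig\tposition\n")
            for name, pos in ann.rrna_sites.as_dict().items():
                fh.write(f"{name}\t{ann.rrna_sites.contig}\t{pos}\n")


def read_annotations(outdir) -> AnnotationSet:
    """Read back the annotation files written by :func:`write_annotations`."""
    from .simdata import Gene, Hairpin, RRNASites, SnoRNA

    outdir = Path(outdir)
    ann = AnnotationSet()
    for line in open(outdir / "genes.bed"):
        contig, start, end, name, _score, strand = line.split()
        ann.genes.append(Gene(contig, strand, int(start), int(end), name))
    for line in open(outdir / "repeats.bed"):
        contig, start, end = line.split()[:3]
        ann.repeats.append((contig, int(start), int(end)))
    for line in open(outdir / "snorna.bed"):
        contig, start, end, name, _score, strand = line.split()
        sno_name, group = name.split(":")
        ann.snornas.append(SnoRNA(contig, strand, int(start), int(end), group, sno_name))
    for line in open(outdir / "hairpins.gff"):
        if line.startswith("#"):
            continue
        contig, _src, _type, start, end, _score, strand, _frame, attrs = line.split("\t")
        fields = dict(kv.split("=") for kv in attrs.strip().split(";"))
        ann.hairpins.append(
            Hairpin(contig, strand, int(start) - 1, int(end), fields["ID"], fields["cluster"])
        )
    rr = pd.read_csv(outdir / "rrna_sites.tsv", sep="\t").set_index("site")
    ann.rrna_sites = RRNASites(
        rr.loc["A_prime", "contig"],
        int(rr.loc["A_prime", "position"]),
        int(rr.loc["A0", "position"]),
        int(rr.loc["site1", "position"]),
    )
    return ann


def write_hits(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample\tcontig\tstrand\tpa_position\tn_candidates\t"
            "mate_contig\tmate_start\tmate_end\tmate_strand\tname\n"
        )
        for h in hits:
            mc, ms, me, mstr = h.five_prime_mate_interval
            fh.write(
                f"{h.sample}\t{h.contig}\t{h.strand}\t{h.pa_position}\t"
                f"{h.n_candidate_positions}\t{mc}\t{ms}\t{me}\t{mstr}\t{h.name}\n"
            )


def read_hits(path) -> list:
    from .mapper import MappedHit

    hits = []
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        hits.append(
            MappedHit(
                sample=row.sample,
                contig=row.contig,
                strand=row.strand,
                pa_position=int(row.pa_position),
                n_candidate_positions=int(row.n_candidates),
                five_prime_mate_interval=(
                    row.mate_contig,
                    int(row.mate_start),
                    int(row.mate_end),
                    row.mate_strand,
                ),
                name=str(row.name),
            )
        )
    return hits


def read_sites(path, samples: list[str]):
    from .sites import PASiteTable

    df = pd.read_csv(path, sep="\t").set_index(["contig", "strand", "position"])
    return PASiteTable(df, samples)


def write_truth(truth: TruthTable, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_sites(table, path) -> None:
    table.df.reset_index().to_csv(path, sep="\t", index=False)


def write_bedgraph(table, sample: str, outdir, stem: str = "sites", raw: bool = True) -> None:
    """Per-sample bedGraph tracks; minus-strand values go to a separate file."""
    col = f"raw_{sample}" if raw else f"rpm_{sample}"
    df = table.df.reset_index()
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        sub = df[(df["strand"] == strand) & (df[col] > 0)]
        with open(Path(outdir) / f"{stem}.{sample}.{suffix}.bedgraph", "w") as fh:
            for _, row in sub.iterrows():
                fh.write(
                    f"{row['contig']}\t{row['position']}\t{row['position'] + 1}\t{row[col]}\n"
                )


def write_clusters(clusters, categories, path) -> None:
    """narrowPeak-style BED of called peaks."""
    with open(path, "w") as fh:
        for cl, cat in zip(clusters, categories):
            lo, hi = int(cl.positions.min()), int(cl.positions.max())
            total = sum(cl.totals.values())
            fh.write(
                f"{cl.contig}\t{lo}\t{hi + 1}\t{cl.name}\t{total}\t{cl.strand}\t"
                f"{cl.mode}\t{cl.width95}\t{int(cl.narrow)}\t{cat}\n"
            )


def records_frame(records) -> pd.DataFrame:
    """Differential records as a report table with 1-based mode coordinates
    and N.D. for control-zero ratios."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["mode"] = d["mode"] + 1
        d["ratio"] = "N.D." if r.ratio is None else round(r.ratio, 2)
        rows.append(d)
    return pd.DataFrame(rows)


def leaders_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = dataclasses.asdict(c)
        d["drosha_site"] = d["drosha_site"] + 1
        if d["modal_position"] is not None:
            d["modal_position"] += 1
        d["ratio"] = "N.D." if c.ratio is None else round(c.ratio, 2)
        rows.append(d)
    return pd.DataFrame(rows)
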