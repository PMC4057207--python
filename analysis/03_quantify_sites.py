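"""Tally adenylation hits into the site table, apply the minimum-read and
templated-adenosine filters, and normalise to reads per million.

Writes sites.tsv and per-sample raw/RPM bedGraph tracks under results/sites/.
"""

import argparse
from pathlib import Path

from pa_surveil import io, sites


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", default="results/simdata", type=Path)
    ap.add_argument("--mapdir", default="results/mapping", type=Path)
    ap.add_argument("--outdir", default="results/sites", type=Path)
    ap.add_argument("--min-reads", default=5, type=int)
    ap.add_argument("--a-run", default=6, type=int)
    ap.add_argument("--a-window", default=20, type=int)
    ap.add_argument("--a-hits", default=15, type=int)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genome = io.read_fasta(args.simdir / "genome.fa")
    hits = io.read_hits(args.mapdir / "hits.tsv")
    samples = sorted({h.sample for h in hits})
    table = sites.tally(hits, samples)
    sites.apply_min_reads(table, args.min_reads)
    sites.filter_templated_a(table, genome, args.a_run, args.a_window, args.a_hits)
    mapped = {s: int(table.raw(s).sum()) for s in samples}
    sites.normalize_rpm(table, mapped)

    n_flagged = int(table.df["templated_a"].sum())
    print(f"{len(table.df):,} sites; {n_flagged} flagged as templated-A internal priming")
    for s in samples:
        print(
            f"{s}: {mapped[s]:,} tallied reads, "
            f"{int((~table.df[f'below_min_{s}']).sum()):,} sites at >= {args.min_reads} reads"
        )
    io.write_sites(table, args.outdir / "sites.tsv")
    for s in samples:
        io.write_bedgraph(table, s, args.outdir, raw=True)


if __name__ == "__main__":
    main()
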