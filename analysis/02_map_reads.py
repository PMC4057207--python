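"""Demultiplex, orient by the TTT tag, and map the simulated libraries.

Reads the FASTQ and genome from results/simdata/, writes accepted
adenylation hits and a mapping summary under results/mapping/.
"""

import argparse
import itertools
from pathlib import Path

from pa_surveil import io, mapper, readprep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/simdata", type=Path)
    ap.add_argument("--outdir", default="results/mapping", type=Path)
    ap.add_argument("--seed", default=1, type=int)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genome = io.read_fasta(args.indir / "genome.fa")
    ann = io.read_annotations(args.indir)
    barcodes = dict(
        line.split() for line in open(args.indir / "barcodes.tsv") if line.strip()
    )
    stream = itertools.chain.from_iterable(
        readprep.iter_fastq_pairs(
            args.indir / f"{s}_R1.fastq", args.indir / f"{s}_R2.fastq"
        )
        for s in barcodes
    )
    demux = readprep.demultiplex(stream, barcodes)
    print("demultiplexed:", demux.counts)

    index = mapper.build_index(genome)
    all_hits, raw_counts = [], {}
    for i, sample in enumerate(sorted(barcodes)):
        oriented, rejected = readprep.orient_pairs(sample, demux.assigned[sample])
        print(f"{sample}: {len(oriented):,} oriented, rejections {rejected}")
        hits, map_rej = mapper.map_reads(
            oriented, index, seed=args.seed * 7919 + i, repeats=ann.repeats
        )
        print(f"{sample}: {len(hits):,} hits, map rejections {map_rej}")
        all_hits.extend(hits)
        raw_counts[sample] = len(demux.assigned[sample])

    summary = mapper.mapping_summary(raw_counts, all_hits)
    print(summary)
    io.write_hits(all_hits, args.outdir / "hits.tsv")
    summary.to_csv(args.outdir / "summary.tsv", sep="\t")


if __name__ == "__main__":
    main()
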