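"""Build the toy genome with planted surveillance targets and simulate the
two-condition PA-seq libraries.

Writes genome.fa, annotation BED/GFF/TSV files, truth.tsv and per-sample
paired FASTQ under results/simdata/.
"""

import argparse
from pathlib import Path

from pa_surveil import io, simdata


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results/simdata", type=Path)
    ap.add_argument("--seed", default=1, type=int)
    ap.add_argument("--n-pairs", default=200_000, type=int)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    layout = simdata.GenomeLayout()
    cfg = simdata.SimConfig(n_read_pairs=args.n_pairs, seed=args.seed)
    genome, ann, truth = simdata.build_toy_genome(layout, seed=args.seed)
    io.write_fasta(genome, args.outdir / "genome.fa")
    io.write_annotations(ann, args.outdir)
    io.write_truth(truth, args.outdir / "truth.tsv")
    print(f"genome: {', '.join(f'{k} {len(v):,} bp' for k, v in genome.contigs.items())}")
    print(f"planted truth sites: {len(truth.records)}")

    for condition in ("control", "kd"):
        pairs = simdata.simulate_paseq_reads(genome, truth, cfg, condition)
        io.write_fastq(
            pairs,
            args.outdir / f"{condition}_R1.fastq",
            args.outdir / f"{condition}_R2.fastq",
            cfg.quality_char,
        )
        print(f"{condition}: {len(pairs):,} read pairs (barcode {cfg.barcodes[condition]})")
    (args.outdir / "barcodes.tsv").write_text(
        "".join(f"{s}\t{b}\n" for s, b in cfg.barcodes.items())
    )


if __name__ == "__main__":
    main()
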