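# Methods

## Problem and model

PA-seq captures the 3′ ends of adenylated RNAs: each sequenced fragment is
reverse-transcribed from the poly(A) tail with an oligo-dT/deoxyU/TTTVN
primer, and USER cleavage leaves a three-T tag immediately adjacent to the
complement of the transcript's 3′-terminal templated residue. A mapped read
pair therefore reports a single genomic coordinate — the adenylation (PA)
site — on a transcript strand. Comparing per-site read counts between an
Mtr4-helicase knockdown (KD) and a control knockdown identifies RNAs that
accumulate when TRAMP/NEXT-mediated exosome surveillance is impaired:
rRNA 5′ETS fragments terminating at the A₀ processing site, snoRNAs
over-trimmed by 1–3 nt at their 3′ ends, and pri-miRNA 5′ leaders whose
adenylated termini coincide with Drosha cleavage sites. Protein-coding mRNA
poly(A) sites serve as the null complement: their KD/control ratios should
centre on 1.

The pipeline implements this analysis end to end and, because the real
sequencing data are not redistributed here, ships a simulator that plants
each target class with known fold changes so recovery is testable.

## Pipeline stages and rules

1. **Read preparation.** Pairs are assigned to samples by perfect match of
   the first five bases of read 1 to a registered barcode (no mismatch
   rescue); the mate opening with exactly `TTT` is the 3′ read and exactly
   three T's are trimmed (a fourth leading T is templated — the complement
   of a terminal A is excluded by the V anchor). Pairs where both or
   neither mate carries the tag are rejected with distinct reason codes;
   post-trim reads shorter than 8 nt are dropped.
2. **Mapping.** A k-mer index (k = 12) with pigeonhole seeding (three
   disjoint seeds; complete for ≤ 2 mismatches) finds every placement of the
   3′ read; a placement counts as a candidate only if the 5′ mate aligns
   (≤ 2 mismatches) on the opposite genomic strand, inward-facing, within a
   1000 bp span on the same contig. Zero candidates → unmapped; ≥ 10 →
   discarded; 2–9 → one candidate chosen uniformly with a seeded generator.
   A chosen placement overlapping an annotated repeat is discarded; the
   repeat test follows the random assignment so it cannot bias assignment
   uniformity. Mismatches are counted on the templated portion only, and
   indels are not modelled. The PA site is the base adjacent to the trimmed
   tag; the transcript strand is the opposite of the 3′ read's alignment
   strand.
3. **Site table.** Hits are tallied per (contig, strand, position) and
   sample. Sites with fewer than 5 reads in a sample are flagged for that
   sample (directed feature queries may bypass the flag — mirroring the
   original study's directed interrogation of sub-threshold positions).
   The internal-priming rule flags a site when the 20 genomic bases
   immediately downstream in transcript orientation contain ≥ 6 consecutive
   adenosines or ≥ 15 in total; flagged sites are excluded from all peak and
   differential computations. The window is strictly downstream (+1..+20),
   anchored per site rather than per cluster, because internal priming
   mimics a tail 3′ of the apparent end; truncated windows at contig edges
   scale both thresholds proportionally (ceiling). Counts are normalised to
   reads per million mapped reads of the same run; no cross-sample
   normalisation is applied.
4. **Peak calling.** Retained sites are smoothed with a Gaussian kernel,
   bandwidth 5 bp (PA ends are near-single-nucleotide; DNase-scale defaults
   would be inappropriate). The calling threshold defaults to the density a
   lone 5-read site produces two bandwidths away, so every retained site
   joins exactly one cluster. A cluster's mode is its highest-count member
   in the focal sample (ties break to the most 5′ position in transcript
   orientation). The 95 % interval is the tightest central interval of the
   read-position multiset — low end: smallest position with strictly more
   than 2.5 % of reads at or below it; high end: smallest position with at
   least 97.5 % — and a peak is *narrow* when that interval is under 10 bp
   wide. Windowed sums cover mode ± 2 (five positions) and are directed raw
   queries: they include sub-threshold neighbours, so they can exceed the
   cluster's retained-member total for a sample. The "+2 bp" of the source
   tables is read as ± 2 throughout.
5. **Differential and feature anchoring.** Per-gene modal PA sites are the
   maximum-pooled-count retained site within ± 50 bases of the annotated 3′
   end (ties → closest to the end, then most 5′), reported when the focal
   sample has ≥ 5 reads there. Reproducibility is the squared Pearson
   correlation of log₁₀ RPM over genes positive in both samples (zeros
   excluded and counted separately; an anti-correlated pair is flagged by
   the slope sign). The log₂ histogram uses a symmetric centre bin
   [−0.2, +0.2] and 0.4-wide bins labelled by their outer edge. Peaks are
   categorised by precedence — annotated poly(A) site (mode within ± 50 of
   a gene end, matching strand), else repeat, else neither — and "neither"
   peaks are ranked by the KD/control ratio of their mode ± 2 sums;
   control-zero entries are reported N.D. (ranked above finite ratios), and
   no significance testing or multiple-testing correction is applied, by
   design: the analysis ranks by raw ratio only. The miRNA leader scan
   takes the Drosha site from the hairpin annotation (base immediately 5′
   of the hairpin in transcript orientation) and sums raw reads over ± 2,
   bypassing the minimum-read flag. Positional profiles report counts by
   offset from feature 3′ ends (offset 0 = last annotated base, negative =
   inside the feature), pooled over identical tandem copies, which also
   neutralises the random assignment of multimapping reads among those
   copies. A QC statistic reports the fraction of 5′ mates fully contained
   in a feature, separating bona fide processing from read-through.

## Simulator

The toy genome (default 26 kb + 14 kb contigs) carries: 30 protein-coding
genes (alternating strands, log-uniform abundances 50–2000 weight units,
fold 1), two host transcripts with pri-miRNA hairpins (one minus-strand
two-hairpin cluster, one plus-strand singleton), an rRNA unit with named
A′/A₀/18S-junction coordinates, four identical tandem 214 bp snoRNA copies,
three unannotated ("orphan") PA sites that the categoriser must class as
"neither" (fold 1 — the null peaks for ranking tests), two internal-priming
traps sitting immediately 5′ of planted 8-base genomic A-runs, and a
12-copy 250 bp repeat family (both mates of a pair fit inside one copy, so
such pairs genuinely have 12 candidate placements). Planted fold changes
are the study conditions: miRNA leaders 60, snoRNA −1..−3 offsets 9, A₀ 8.

Reads: 2 × 10⁵ pairs per condition by default, 50 nt, fragments 100–180 bp
(within the protocol's size-selection window), substitution errors at
10⁻³/base, constant qualities. Each pair derives from a truth site;
the 3′ end jitters by ± 1 base with total probability 0.1 (never onto an A —
the V anchor of the RT primer cannot leave a terminal A — and the
transcript-strand bases at [site−1, site+21] of every true site are
generated non-A, which both preserves the tag invariant under jitter and
guarantees true sites never trigger the templated-A rule). Which mate is
read 1 is random; read 1 is prefixed with the sample barcode; errors are
applied after assembly, so barcodes and tags can be corrupted, exercising
the unassigned and rejection paths.

Sampling is multinomial to a fixed depth per sample, so the expected
KD/control count ratio at a planted site is the fold divided by the ratio
of total condition weights (≈ fold/1.06 under the default layout).
`expected_counts` and `expected_window_counts` give the exact expectations
(the latter redistributes the ± 1 jitter mass, including leakage between
neighbouring planted sites); recovery tests are centred on these model
expectations, not the nominal fold. Where several folds are checked
simultaneously, intervals use z = 3 (family-wise ≈ 99 % over four checks)
around the expected log-ratio with variance 1/E_KD + 1/E_ctrl.

What the simulator does **not** emulate: PCR duplicates, adapter
read-through, quality-score structure, indels, RNA-fragmentation or
coverage biases, poly(A)-tail length, and real mammalian genome complexity
(repeat families beyond the planted ones, isoform structure). Passing tests
therefore demonstrate correctness of the pipeline's rules and estimators
under the stated sampling model, not performance on real libraries.

## Numerical and design choices

- Coordinates are 0-based half-open internally and in BED; GFF and report
  tables convert at the boundary (1-based).
- The mapper is an exact seed-and-verify implementation sized for toy
  genomes; ≥ 10-candidate reads are discarded (random assignment is only
  licensed for fewer than ten), and a brute-force scan over every genomic
  offset serves as its oracle in tests.
- Peak calling is a direct Gaussian-KDE re-implementation of
  density-clustering; no attempt is made to reproduce any external
  program's numeric output — only the narrow-peak definition and the
  downstream use of modes and windows are contractual.
- Mate-role swaps are possible when an error destroys the TTT tag while the
  5′ mate genuinely opens with genomic TTT; at default settings this
  affects ~5 × 10⁻⁵ of pairs and is tolerated (tests bound it at 0.1 %).
- Problem sizes in the test suite: unit tests run a 30 k-pair pipeline,
  recovery tests a 2 × 10⁵-pair pipeline per condition, and the mapper
  oracle a 50 kb genome with 10⁴ pairs — depths at which every planted
  fold's sampling interval is well separated from the null.

## Known limitations

- The per-site (rather than per-cluster) anchoring of the templated-A rule
  and the ± 2 reading of the "+2 bp" window are documented interpretations;
  both are configurable.
- No statistical testing is attached to ratios; N.D. entries cannot be
  ranked quantitatively against finite ratios.
- The mapper supports substitutions only; reads with indels are unmapped.
- RPM is the only normalisation; composition effects between conditions are
  therefore visible in raw ratios (see the expected-ratio oracle above).
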