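"""End-to-end orchestration: simulate -> demux -> orient -> map -> sites ->
peaks -> differential/feature analyses.

`run_pipeline` executes the whole chain in memory on the toy genome and
returns every intermediate plus the headline metrics; the numbered scripts
under ``analysis/`` are thin drivers over this function and the individual
module entry points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import diffannot, mapper, peaks, readprep, simdata, sites

SAMPLES = ("control", "kd")


@dataclass
class PipelineResult:
    genome: simdata.ToyGenome
    annotations: simdata.AnnotationSet
    truth: simdata.TruthTable
    config: simdata.SimConfig
    demux_counts: dict[str, int]
    orient_rejections: dict[str, dict[str, int]]
    hits: dict[str, list]
    map_rejections: dict[str, dict[str, int]]
    summary: pd.DataFrame
    table: sites.PASiteTable
    clusters: list
    categories: list[str]
    modal: pd.DataFrame
    records: list
    leaders: list
    metrics: dict = field(default_factory=dict)


def run_pipeline(
    layout: simdata.GenomeLayout | None = None,
    cfg: simdata.SimConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full PA-seq analysis on freshly simulated two-condition data.

    `seed` drives genome construction, read simulation and multimap
    assignment through independent deterministic substreams.
    """
    layout = layout or simdata.GenomeLayout()
    cfg = cfg or simdata.SimConfig(seed=seed)
    genome, ann, truth = simdata.build_toy_genome(layout, seed=seed)

    raw = []
    for condition in SAMPLES:
        raw.extend(simdata.simulate_paseq_reads(genome, truth, cfg, condition))
    demux = readprep.demultiplex(raw, cfg.barcodes)

    oriented: dict[str, list] = {}
    orient_rej: dict[str, dict[str, int]] = {}
    for sample in SAMPLES:
        oriented[sample], orient_rej[sample] = readprep.orient_pairs(
            sample, demux.assigned[sample]
        )

    index = mapper.build_index(genome)
    params = mapper.MapParams()
    hits: dict[str, list] = {}
    map_rej: dict[str, dict[str, int]] = {}
    for i, sample in enumerate(SAMPLES):
        hits[sample], map_rej[sample] = mapper.map_reads(
            oriented[sample],
            index,
            params,
            seed=(seed * 7919 + i) % 2**31,
            repeats=ann.repeats,
        )
    all_hits = [h for sample in SAMPLES for h in hits[sample]]
    raw_counts = {s: len(demux.assigned[s]) for s in SAMPLES}
    summary = mapper.mapping_summary(raw_counts, all_hits)

    table = sites.tally(all_hits, samples=list(SAMPLES))
    sites.apply_min_reads(table)
    sites.filter_templated_a(table, genome)
    mapped_totals = {s: len(hits[s]) for s in SAMPLES}
    sites.normalize_rpm(table, mapped_totals)

    clusters = peaks.call_clusters(table, "kd")
    categories = diffannot.categorize_peaks(clusters, ann.genes, ann.repeats)
    records = diffannot.rank_neither(clusters, categories, "kd", "control")
    leaders = diffannot.mirna_leader_scan(table, ann.hairpins, "kd", "control")
    modal = diffannot.refseq_modal_sites(table, ann.genes, "kd", "control")

    metrics: dict = {}
    if len(modal) >= 3:
        r2, positive = diffannot.scatter_r2(
            modal["kd_rpm"].to_numpy(), modal["ctrl_rpm"].to_numpy()
        )
        metrics["modal_r2"] = r2
        metrics["modal_r2_positive_slope"] = positive
        ratios = [
            diffannot.differential_ratio(k, c)
            for k, c in zip(modal["kd_reads"], modal["ctrl_reads"])
        ]
        log2s = [None if r is None else math.log2(r) for r in ratios]
        _, frac, n_nd = diffannot.log2_histogram(log2s)
        metrics["frac_within_twofold"] = frac
        metrics["n_modal_genes"] = len(modal)
        metrics["n_modal_nd"] = n_nd

    if ann.snornas:
        profile = diffannot.positional_profile(
            table, ann.snornas, list(SAMPLES), offset_range=(-6, 3)
        )
        metrics["u3_profile"] = profile
        metrics["u3_offset_fold"] = diffannot.cumulative_offset_ratio(
            profile, "kd", "control", -3, -1
        )
    if ann.rrna_sites is not None:
        a0 = ann.rrna_sites.a0
        kd = table.directed_counts("chr2", "+", a0 - 2, a0 + 2, "kd")
        ctrl = table.directed_counts("chr2", "+", a0 - 2, a0 + 2, "control")
        metrics["a0_fold"] = diffannot.differential_ratio(kd, ctrl)
        metrics["a0_kd_reads"], metrics["a0_ctrl_reads"] = kd, ctrl

    qc = {}
    for sno in ann.snornas:
        frac = diffannot.five_prime_mate_qc(all_hits, sno.contig, sno.start, sno.end)
        if frac is not None:
            qc[sno.name] = frac
    metrics["snorna_5p_mate_containment"] = qc

    return PipelineResult(
        genome=genome,
        annotations=ann,
        truth=truth,
        config=cfg,
        demux_counts=demux.counts,
        orient_rejections=orient_rej,
        hits=hits,
        map_rejections=map_rej,
        summary=summary,
        table=table,
        clusters=clusters,
        categories=categories,
        modal=modal,
        records=records,
        leaders=leaders,
        metrics=metrics,
    )
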