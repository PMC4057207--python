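"""Differential records, histogram bins, categorisation, feature scans."""

import numpy as np
import pandas as pd
import pytest

from pa_surveil import diffannot
from pa_surveil.diffannot import (
    CATEGORY_NEITHER,
    CATEGORY_REFSEQ,
    CATEGORY_REPEAT,
    categorize_peaks,
    cumulative_offset_ratio,
    differential_ratio,
    five_prime_mate_qc,
    log2_bin_label,
    log2_histogram,
    mirna_leader_scan,
    positional_profile,
    rank_neither,
    refseq_modal_sites,
    scatter_r2,
)
from pa_surveil.mapper import MappedHit
from pa_surveil.peaks import PeakCluster
from pa_surveil.simdata import Gene, Hairpin, SnoRNA
from pa_surveil.sites import PASiteTable, apply_min_reads, tally


def make_table(rows, samples=("kd", "control")):
    """rows: {(contig, strand, pos): {sample: count}}"""
    hits = []
    for (contig, strand, pos), by_sample in rows.items():
        for s, n in by_sample.items():
            hits += [MappedHit(s, contig, strand, pos, 1, (contig, 0, 50, "+"))] * n
    t = tally(hits, list(samples))
    apply_min_reads(t)
    t.df["templated_a"] = False
    return t


def make_cluster(contig, strand, mode, kd, ctrl):
    return PeakCluster(
        contig=contig,
        strand=strand,
        positions=np.array([mode]),
        counts=pd.DataFrame(),
        mode=mode,
        interval95=(mode, mode),
        width95=1,
        narrow=True,
        totals={"kd": kd, "control": ctrl},
        window_sums={"kd": kd, "control": ctrl},
    )


class TestRatios:
    @pytest.mark.parametrize(
        "kd,ctrl,expected",
        [(250, 4, 62.5), (332, 43, 7.72), (40, 6, 6.67), (65, 1, 65.0)],
    )
    def test_window_sum_ratios(self, kd, ctrl, expected):
        assert round(differential_ratio(kd, ctrl), 2) == expected

    def test_control_zero_is_not_detected(self):
        assert differential_ratio(10, 0) is None


class TestModalSites:
    def test_site_at_annotated_end(self):
        gene = Gene("c", "+", 100, 500, "g")
        t = make_table({("c", "+", 499): {"kd": 20, "control": 18}})
        out = refseq_modal_sites(t, [gene], "kd", "control")
        assert out.iloc[0]["modal_position"] == 499
        assert out.iloc[0]["kd_reads"] == 20

    def test_window_boundary_excludes_past_50(self):
        gene = Gene("c", "+", 100, 500, "g")
        inside = make_table({("c", "+", 549): {"kd": 20, "control": 5}})
        outside = make_table({("c", "+", 550): {"kd": 20, "control": 5}})
        assert len(refseq_modal_sites(inside, [gene], "kd", "control")) == 1
        assert len(refseq_modal_sites(outside, [gene], "kd", "control")) == 0

    def test_modal_requires_five_reads_in_focal_sample(self):
        gene = Gene("c", "+", 100, 500, "g")
        t = make_table({("c", "+", 499): {"kd": 4, "control": 50}})
        assert len(refseq_modal_sites(t, [gene], "kd", "control")) == 0

    def test_tie_breaks_to_closest_then_most_five_prime(self):
        gene = Gene("c", "+", 100, 500, "g")
        t = make_table(
            {
                ("c", "+", 490): {"kd": 10, "control": 10},
                ("c", "+", 499): {"kd": 10, "control": 10},
            }
        )
        out = refseq_modal_sites(t, [gene], "kd", "control")
        assert out.iloc[0]["modal_position"] == 499


class TestScatterR2:
    def test_identical_vectors(self):
        r2, pos = scatter_r2(np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 4.0]))
        assert r2 == pytest.approx(1.0)
        assert pos

    def test_anticorrelated_flagged_negative(self):
        r2, pos = scatter_r2(np.array([1, 2, 3.0]), np.array([3, 2, 1.0]), log=False)
        assert r2 == pytest.approx(1.0)
        assert not pos

    def test_zeros_excluded_and_minimum_enforced(self):
        with pytest.raises(ValueError):
            scatter_r2(np.array([1.0, 2, 0, 0]), np.array([1.0, 2, 3, 4]))


class TestHistogram:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.1, "0"),
            (0.2, "0"),
            (-0.2, "0"),
            (0.5, "+0.6"),
            (0.6, "+0.6"),
            (0.61, "+1.0"),
            (-0.5, "-0.6"),
            (1.3, "+1.4"),
        ],
    )
    def test_bin_labels(self, value, label):
        assert log2_bin_label(value) == label

    def test_histogram_counts_and_fraction(self):
        counts, frac, n_nd = log2_histogram([0.0, 0.1, 0.5, -0.5, 1.5, None])
        assert counts["0"] == 2
        assert counts["+0.6"] == 1 and counts["-0.6"] == 1
        assert frac == pytest.approx(4 / 5)
        assert n_nd == 1


class TestCategorise:
    def test_precedence(self):
        genes = [Gene("c", "+", 100, 500, "g")]
        repeats = [("c", 2000, 3000)]
        clusters = [
            make_cluster("c", "+", 499, 10, 10),  # at annotated end
            make_cluster("c", "+", 2500, 10, 10),  # inside repeat
            make_cluster("c", "+", 5000, 10, 10),  # neither
            make_cluster("c", "-", 499, 10, 10),  # wrong strand for the gene
        ]
        cats = categorize_peaks(clusters, genes, repeats)
        assert cats == [CATEGORY_REFSEQ, CATEGORY_REPEAT, CATEGORY_NEITHER, CATEGORY_NEITHER]

    def test_partition_is_total(self, small_run):
        res = small_run
        assert len(res.categories) == len(res.clusters)
        assert set(res.categories) <= {CATEGORY_REFSEQ, CATEGORY_REPEAT, CATEGORY_NEITHER}


class TestRankNeither:
    def test_ratio_ordering_and_nd_rank(self):
        clusters = [
            make_cluster("c", "+", 1, 40, 6),
            make_cluster("c", "+", 2, 250, 4),
            make_cluster("c", "+", 3, 30, 0),
        ]
        records = rank_neither(clusters, [CATEGORY_NEITHER] * 3, "kd", "control")
        assert [r.ratio for r in records] == [None, 62.5, 40 / 6]
        drop_nd = rank_neither(
            clusters, [CATEGORY_NEITHER] * 3, "kd", "control", include_nd=False
        )
        assert [r.ratio for r in drop_nd] == [62.5, 40 / 6]

    def test_ratio_consistency(self, small_run):
        for r in small_run.records:
            if r.ratio is not None:
                assert r.ratio * r.ctrl_reads == pytest.approx(r.kd_reads)


class TestLeaderScan:
    def test_plus_and_minus_drosha_site_geometry(self):
        hp_plus = Hairpin("c", "+", 100, 160, "mp", "cl")
        hp_minus = Hairpin("c", "-", 100, 160, "mm", "cl")
        assert hp_plus.drosha_site == 99
        assert hp_minus.drosha_site == 160

    def test_directed_query_bypasses_min_reads(self):
        hp = Hairpin("c", "+", 100, 160, "m", "cl")
        t = make_table({("c", "+", 99): {"kd": 3, "control": 1}})
        calls = mirna_leader_scan(t, [hp], "kd", "control")
        assert calls[0].kd_reads == 3 and calls[0].ctrl_reads == 1

    def test_silent_hairpin_suppressed(self):
        hp = Hairpin("c", "+", 100, 160, "m", "cl")
        t = make_table({("c", "+", 500): {"kd": 10, "control": 10}})
        assert mirna_leader_scan(t, [hp], "kd", "control") == []
        assert len(mirna_leader_scan(t, [hp], "kd", "control", include_all=True)) == 1

    def test_control_only_reads_report_depletion_not_accumulation(self):
        hp = Hairpin("c", "+", 100, 160, "m", "cl")
        t = make_table({("c", "+", 99): {"kd": 2, "control": 20}})
        call = mirna_leader_scan(t, [hp], "kd", "control")[0]
        assert call.ratio < 1

    def test_planted_leaders_recovered_exactly(self, small_run):
        res = small_run
        calls = {c.mirna: c for c in res.leaders}
        assert set(calls) == {"mirA", "mirC"}  # the silent hairpin is suppressed
        for c in calls.values():
            assert c.modal_position == c.drosha_site
            assert c.ratio > 10


class TestPositionalProfile:
    def test_reads_at_annotated_end_only(self):
        sno = SnoRNA("c", "+", 100, 200, "grp", "s1")
        t = make_table({("c", "+", 199): {"kd": 7, "control": 7}})
        prof = positional_profile(t, [sno], ["kd", "control"], (-3, 3))
        assert prof.loc[0, "kd"] == 7
        assert prof.drop(index=0).values.sum() == 0

    def test_minus_strand_offset_arithmetic(self):
        """On a 30 bp minus-strand feature, genomic position end3 - k maps
        to offset +k (beyond the 3' end)."""
        feat = SnoRNA("c", "-", 100, 130, "grp", "s1")
        t = make_table(
            {
                ("c", "-", 100): {"kd": 5, "control": 5},  # offset 0
                ("c", "-", 97): {"kd": 3, "control": 3},  # offset +3
                ("c", "-", 102): {"kd": 2, "control": 2},  # offset -2
            }
        )
        prof = positional_profile(t, [feat], ["kd"], (-3, 3))
        assert prof.loc[0, "kd"] == 5
        assert prof.loc[3, "kd"] == 3
        assert prof.loc[-2, "kd"] == 2

    def test_pooling_over_identical_copies(self):
        copies = [SnoRNA("c", "+", 100, 200, "grp", "a"), SnoRNA("c", "+", 300, 400, "grp", "b")]
        t = make_table(
            {
                ("c", "+", 199): {"kd": 4, "control": 1},
                ("c", "+", 399): {"kd": 6, "control": 2},
            }
        )
        prof = positional_profile(t, copies, ["kd", "control"], (-2, 2))
        assert prof.loc[0, "kd"] == 10 and prof.loc[0, "control"] == 3

    def test_cumulative_ratio(self):
        prof = pd.DataFrame(
            {"kd": [90, 45, 45, 100], "control": [10, 5, 5, 100]},
            index=pd.Index([-3, -2, -1, 0], name="offset"),
        )
        assert cumulative_offset_ratio(prof, "kd", "control", -3, -1) == 9.0


class TestFivePrimeMateQC:
    def test_counts_containment(self):
        hits = [
            MappedHit("s", "c", "+", 150, 1, ("c", 110, 160, "+")),
            MappedHit("s", "c", "+", 150, 1, ("c", 110, 160, "+")),
            MappedHit("s", "c", "+", 150, 1, ("c", 110, 160, "+")),
            MappedHit("s", "c", "+", 150, 1, ("c", 90, 140, "+")),  # leaks upstream
        ]
        assert five_prime_mate_qc(hits, "c", 100, 200) == 0.75

    def test_no_hits_is_undefined(self):
        assert five_prime_mate_qc([], "c", 100, 200) is None

    def test_read_through_detected_by_fraction_below_one(self, small_run):
        res = small_run
        qc = res.metrics["snorna_5p_mate_containment"]
        assert set(qc) == {"U3B.1", "U3B.2", "U3B.3", "U3B.4"}
        for frac in qc.values():
            assert frac >= 0.99
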