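"""MTPT detection, intact-gene annotation, summaries and binned correlation."""

import math

import numpy as np
import pytest

from mitokit.cp_transfer import (
    CpSegment,
    annotate_intact_genes,
    binned_feature_correlation,
    build_bin_table,
    detect_cp_segments,
    pearson_two_pass,
    segment_summaries,
    total_cp_content,
)
from mitokit.genome_io import GeneFeature, IsoformRecord, OrganelleGenome
from mitokit.synth import (
    MtptPlan,
    PlastomeConfig,
    SynthConfig,
    generate_mitogenome,
    generate_plastome,
)


class TestDetect:
    def test_planted_mtpts_recovered(self, small_mito, small_plastome):
        genome, truth = small_mito
        plastome, _ = small_plastome
        segs = detect_cp_segments(genome, plastome)
        assert len(segs) == len(truth.mtpts)
        for m in truth.mtpts:
            match = [
                s
                for s in segs
                if s.isoform_id == m.isoform_id and abs(s.start - m.start) <= 13
            ]
            assert match, f"planted MTPT {m} missed"
            s = match[0]
            overlap = min(s.end, m.end) - max(s.start, m.start)
            assert overlap >= 0.95 * (m.end - m.start)
            assert abs(s.identity - m.identity) <= 1.5

    def test_short_transfer_below_length_threshold_not_reported(self, small_plastome):
        plastome, _ = small_plastome
        cfg = SynthConfig(
            n_isoforms=1,
            isoform_length_range=(30_000, 30_000),
            mtpt_plan=[MtptPlan(150, 95.0)],
            seed=19,
        )
        g, truth = generate_mitogenome(cfg, plastome)
        assert truth.mtpts[0].end - truth.mtpts[0].start == 150
        assert detect_cp_segments(g, plastome) == []

    def test_total_invariant_under_isoform_reordering(self, small_mito, small_plastome):
        genome, _ = small_mito
        plastome, _ = small_plastome
        total1, _ = total_cp_content(detect_cp_segments(genome, plastome), genome)
        flipped = OrganelleGenome(genome.name, list(genome)[::-1])
        total2, _ = total_cp_content(detect_cp_segments(flipped, plastome), flipped)
        assert total1 == total2 > 0

    def test_adjacent_hits_merged_and_merge_idempotent(self):
        from mitokit.align import AlignmentHit

        g = OrganelleGenome("m", [IsoformRecord("i", "A" * 50_000, circular=False)])
        p = OrganelleGenome("p", [IsoformRecord("plastome", "C" * 20_000, circular=True)])
        hits = [
            AlignmentHit("i", "p", 1000, 1400, 0, 400, "+", 400, 90.0, 400, 1e-30),
            AlignmentHit("i", "p", 1400, 1800, 400, 800, "+", 400, 86.0, 400, 1e-30),
            AlignmentHit("i", "p", 5000, 5300, 900, 1200, "+", 300, 95.0, 300, 1e-20),
        ]
        segs = detect_cp_segments(g, p, hits=hits)
        assert [(s.start, s.end) for s in segs] == [(1000, 1800), (5000, 5300)]
        assert segs[0].identity == pytest.approx(88.0)  # length-weighted mean
        # idempotence: feeding the merged segments back as hits changes nothing
        hits2 = [
            AlignmentHit("i", "p", s.start, s.end, s.plastome_start, s.plastome_end, s.strand, s.length, s.identity, s.length, 1e-30)
            for s in segs
        ]
        segs2 = detect_cp_segments(g, p, hits=hits2)
        assert [(s.start, s.end) for s in segs2] == [(s.start, s.end) for s in segs]


class TestIntactGenes:
    def _segment(self, ps, pe):
        return CpSegment("i", 0, pe - ps, ps, pe, "+", 95.0)

    def test_contained_gene_intact(self):
        genes = [GeneFeature("psbA", "plastome", 100, 400)]
        intact, frags = annotate_intact_genes([self._segment(50, 500)], genes)
        assert intact == {0: ["psbA"]} and frags == {}

    def test_straddling_gene_is_fragment(self):
        genes = [GeneFeature("rbcL", "plastome", 100, 700)]
        intact, frags = annotate_intact_genes([self._segment(50, 500)], genes)
        assert intact == {} and frags == {0: ["rbcL"]}

    def test_synthetic_mtpt_over_plastome_genes(self):
        plastome, ptruth = generate_plastome(
            PlastomeConfig(lsc_length=20_000, ir_length=3_000, ssc_length=4_000, n_genes=8, seed=23)
        )
        # donor window spanning two full genes and cutting a third
        g1, g2, g3 = ptruth.genes[0], ptruth.genes[1], ptruth.genes[2]
        d0 = max(0, g1.start - 50)
        d1 = g3.start + (g3.length // 2)
        cfg = SynthConfig(
            n_isoforms=1,
            isoform_length_range=(40_000, 40_000),
            mtpt_plan=[MtptPlan(d1 - d0, 92.0, donor_start=d0)],
            seed=23,
        )
        mito, _ = generate_mitogenome(cfg, plastome)
        segs = detect_cp_segments(mito, plastome)
        assert len(segs) == 1
        intact, frags = annotate_intact_genes(segs, ptruth.genes)
        assert set(intact.get(0, [])) == {g1.gene_name, g2.gene_name}
        assert frags.get(0) == [g3.gene_name]


class TestSummaries:
    def _seg(self, length, iso="iso1"):
        return CpSegment(iso, 0, length, 0, length, "+", 90.0)

    def test_default_length_bins(self):
        g = OrganelleGenome("m", [IsoformRecord("iso1", "A" * 1000)])
        hist, per_iso = segment_summaries(
            [self._seg(250), self._seg(800), self._seg(800)], g
        )
        assert hist["n_segments"].tolist() == [1, 2, 0, 0, 0]
        assert per_iso["n_segments"].tolist() == [3]

    def test_no_segments_all_zero(self):
        g = OrganelleGenome("m", [IsoformRecord("iso1", "A" * 1000)])
        hist, per_iso = segment_summaries([], g)
        assert hist["n_segments"].sum() == 0
        assert per_iso["n_segments"].sum() == 0

    def test_per_isoform_counts(self, small_mito, small_plastome):
        genome, truth = small_mito
        plastome, _ = small_plastome
        segs = detect_cp_segments(genome, plastome)
        _, per_iso = segment_summaries(segs, genome)
        expected = {
            iso.id: sum(1 for m in truth.mtpts if m.isoform_id == iso.id)
            for iso in genome
        }
        got = dict(zip(per_iso["isoform_id"], per_iso["n_segments"]))
        assert got == expected


class TestBinnedCorrelation:
    def _toy_genome(self, seed=29, n=60_000):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), n))
        return OrganelleGenome("m", [IsoformRecord("iso1", seq, circular=False)])

    def test_constant_cp_counts_give_nan(self):
        g = self._toy_genome()
        report, _ = binned_feature_correlation(g, [], {})
        assert math.isnan(report.r_cp_gc)
        assert report.diagnostics

    def test_too_few_bins_rejected(self):
        g = OrganelleGenome("m", [IsoformRecord("iso1", "ACGT" * 1000)])
        with pytest.raises(ValueError, match="bins"):
            binned_feature_correlation(g, [], {}, bin_size=3000)

    def test_planted_low_gc_bias_gives_negative_r(self):
        # two isoforms, MTPTs planted only in the AT-rich one
        rng = np.random.default_rng(31)
        low = "".join(rng.choice(list("ACGT"), 45_000, p=[0.35, 0.15, 0.15, 0.35]))
        high = "".join(rng.choice(list("ACGT"), 45_000, p=[0.15, 0.35, 0.35, 0.15]))
        g = OrganelleGenome(
            "m",
            [IsoformRecord("low", low, circular=False), IsoformRecord("high", high, circular=False)],
        )
        segs = [CpSegment("low", s, s + 1200, 0, 1200, "+", 90.0) for s in range(2000, 40_000, 9000)]
        report, bins = binned_feature_correlation(g, segs, {})
        assert report.r_cp_gc < 0
        # magnitude cross-checked against the textbook two-pass formula
        t = bins.table
        expected = pearson_two_pass(t["n_cp"].to_numpy(), t["gc"].to_numpy())
        assert report.r_cp_gc == pytest.approx(expected, abs=1e-12)

    def test_overlap_counting_increments_every_spanned_bin(self):
        g = self._toy_genome(n=30_000)
        seg = CpSegment("iso1", 2_500, 9_500, 0, 7_000, "+", 90.0)
        bt = build_bin_table(g, [seg], {}, bin_size=3000, count_mode="overlap")
        assert bt.table["n_cp"].tolist()[:4] == [1, 1, 1, 1]
        bt2 = build_bin_table(g, [seg], {}, bin_size=3000, count_mode="start")
        assert bt2.table["n_cp"].tolist()[:4] == [1, 0, 0, 0]

    def test_trailing_partial_bin_dropped(self):
        g = OrganelleGenome("m", [IsoformRecord("iso1", "ACGT" * 2000)])  # 8000 bp
        bt = build_bin_table(g, [], {}, bin_size=3000)
        assert len(bt.table) == 2

    def test_pooled_bins_equal_manual_concatenation(self, small_mito, small_plastome):
        genome, _ = small_mito
        plastome, _ = small_plastome
        segs = detect_cp_segments(genome, plastome)
        r_single, bt = binned_feature_correlation(genome, segs, {})
        r_pooled, bt2 = binned_feature_correlation([genome], [segs], [{}])
        assert r_pooled.n_bins == r_single.n_bins
        if not math.isnan(r_single.r_cp_gc):
            assert r_pooled.r_cp_gc == pytest.approx(r_single.r_cp_gc)
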