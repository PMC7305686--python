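"""Tn5 shifts, interval algebra against per-base oracles, peak annotation,
TSS distances, periodicity and differential accessibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ploidycomp as pc
from ploidycomp.atac import (
    AnnotatedPeak,
    ShiftedRead,
    annotate_peaks,
    deg_atac_overlap,
    differential_accessibility,
    filter_organelle,
    fragment_periodicity,
    gene_accessibility,
    merge_close_peaks,
    reproducible_peaks,
    shift_reads,
    tss_distance_cdf,
)
from ploidycomp.io import GeneModel, Interval


def _gene(gene_id="g1", start=10_000, end=13_000, strand="+", chrom="3L"):
    tss = start if strand == "+" else end - 1
    tts = end - 1 if strand == "+" else start
    atg = start + 300 if strand == "+" else end - 301
    return GeneModel(gene_id, chrom, start, end, strand, tss, tts, atg,
                     exons=[(start, end)])


class TestShiftReads:
    def test_forward_plus_four(self):
        (out,) = shift_reads([ShiftedRead("c", 100, 150, "+")])
        assert (out.start, out.end) == (104, 154)

    def test_reverse_minus_five(self):
        (out,) = shift_reads([ShiftedRead("c", 100, 150, "-")])
        assert (out.start, out.end) == (95, 145)

    def test_shift_is_asymmetric_not_an_involution(self):
        fwd = shift_reads([ShiftedRead("c", 1, 30, "+")])[0]
        back = shift_reads([ShiftedRead("c", fwd.start, fwd.end, "-")])[0]
        assert (back.start, back.end) != (1, 30)

    def test_negative_start_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            (out,) = shift_reads([ShiftedRead("c", 2, 30, "-")])
        assert out.start == 0


def test_organelle_read_removal_counts():
    reads = [ShiftedRead("3L", 0, 10, "+"), ShiftedRead("chrM", 0, 10, "+"),
             ShiftedRead("chrC", 5, 15, "-"), ShiftedRead("3L", 20, 40, "-")]
    assert len(filter_organelle(reads, ["chrM", "chrC"])) == 2
    assert filter_organelle(reads, []) == reads


def _coverage(intervals, span):
    cov = np.zeros(span, dtype=bool)
    for iv in intervals:
        cov[iv.start:iv.end] = True
    return cov


class TestReproduciblePeaks:
    def test_three_replicate_example(self):
        reps = [[Interval("c", 0, 10)], [Interval("c", 5, 15)], [Interval("c", 8, 20)]]
        out = reproducible_peaks(reps)
        assert [(iv.start, iv.end) for iv in out] == [(8, 10)]

    def test_identical_replicates_are_identity(self):
        rep = [Interval("c", 5, 50), Interval("c", 100, 130)]
        out = reproducible_peaks([rep, list(rep), list(rep)])
        assert [(iv.start, iv.end) for iv in out] == [(5, 50), (100, 130)]

    def test_disjoint_replicates_empty(self):
        assert reproducible_peaks([[Interval("c", 0, 10)], [Interval("c", 20, 30)]]) == []

    def test_empty_replicate_empty_result(self):
        assert reproducible_peaks([[Interval("c", 0, 10)], []]) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_per_base_boolean_and_oracle(self, seed):
        """On random <=10 kb instances the sweep equals a literal per-base AND."""
        rng = np.random.default_rng(seed)
        span = 10_000
        reps = []
        for _ in range(3):
            rep = []
            for _ in range(rng.integers(3, 12)):
                s = int(rng.integers(0, span - 200))
                rep.append(Interval("c", s, s + int(rng.integers(20, 200))))
            reps.append(rep)
        out = reproducible_peaks(reps)
        oracle = np.logical_and.reduce([_coverage(r, span) for r in reps])
        np.testing.assert_array_equal(_coverage(out, span), oracle)
        # emitted intervals are maximal runs: no two touch
        for a, b in zip(out, out[1:]):
            assert b.start > a.end


class TestMergeClosePeaks:
    def test_gap_nine_merges(self):
        out = merge_close_peaks([Interval("c", 0, 10), Interval("c", 19, 30)])
        assert [(iv.start, iv.end) for iv in out] == [(0, 30)]

    def test_gap_ten_does_not_merge(self):
        out = merge_close_peaks([Interval("c", 0, 10), Interval("c", 20, 30)])
        assert len(out) == 2

    def test_transitive_chain_collapses(self):
        peaks = [Interval("c", 0, 10), Interval("c", 15, 25), Interval("c", 30, 40)]
        out = merge_close_peaks(peaks)  # gaps 5 and 5
        assert [(iv.start, iv.end) for iv in out] == [(0, 40)]

    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 300)),
                    min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_gap_postcondition(self, raw):
        peaks = [Interval("c", s, s + w) for s, w in raw]
        once = merge_close_peaks(peaks)
        twice = merge_close_peaks(once)
        assert once == twice
        for a, b in zip(once, once[1:]):
            assert b.start - a.end >= 10

    def test_coverage_preserved(self):
        rng = np.random.default_rng(5)
        peaks = [Interval("c", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 5000, 40), rng.integers(1, 400, 40))]
        merged = merge_close_peaks(peaks, max_gap=1)
        np.testing.assert_array_equal(_coverage(merged, 6000) & _coverage(peaks, 6000),
                                      _coverage(peaks, 6000))


class TestAnnotatePeaks:
    def test_peak_one_kb_upstream_of_atg_is_promoter(self):
        g = _gene()  # + strand, atg=10300
        (ann,) = annotate_peaks([Interval("3L", 9200, 9400)], [g])
        assert ann.region_class == "promoter5utr" and ann.assigned_gene_id == "g1"

    def test_far_peak_is_intergenic_with_tss_distance(self):
        g = _gene()
        (ann,) = annotate_peaks([Interval("3L", 20_000, 20_200)], [g])
        assert ann.region_class == "intergenic" and ann.assigned_gene_id is None
        assert ann.tss_distance == pytest.approx(10_100.0)

    @pytest.mark.parametrize("span,winner", [
        ((10_200, 10_500), "promoter5utr"),     # straddles promoter + CDS
        ((12_900, 13_400), "cds_intron"),       # straddles CDS + downstream
        ((9_500, 15_100), "promoter5utr"),      # covers everything
    ])
    def test_precedence_over_class_pairs(self, span, winner):
        g = _gene()
        (ann,) = annotate_peaks([Interval("3L", *span)], [g])
        assert ann.region_class == winner

    def test_minus_strand_promoter_is_downstream_in_genomic_coordinates(self):
        g = _gene(strand="-")  # atg = 12699
        (ann,) = annotate_peaks([Interval("3L", 13_500, 13_700)], [g])
        assert ann.region_class == "promoter5utr"
        # strand-signed distance: peak lies 5' of the TSS at 12999
        assert ann.tss_distance < 0

    def test_multi_gene_overlap_resolves_to_nearest_tss(self):
        g1 = _gene("g1", 10_000, 13_000)
        g2 = _gene("g2", 15_200, 18_000)
        # peak in the shared window between g1 downstream and g2 promoter
        (ann,) = annotate_peaks([Interval("3L", 14_900, 15_100)], [g1, g2])
        assert ann.assigned_gene_id == "g2"

    def test_each_peak_gets_exactly_one_class(self, small_genomes, cfg_small):
        genes, _, _ = small_genomes
        reps, _ = pc.synth.generate_atac(cfg_small, genes, "diploid")
        peaks = merge_close_peaks(reproducible_peaks(reps))
        anns = annotate_peaks(peaks, genes)
        assert len(anns) == len(peaks)
        assert all(a.region_class in pc.atac.REGION_CLASSES for a in anns)
        assert all((a.region_class == "intergenic") == (a.assigned_gene_id is None)
                   for a in anns)

    def test_mirror_invariance_of_class_counts(self, small_genomes, cfg_small):
        genes, _, _ = small_genomes
        reps, _ = pc.synth.generate_atac(cfg_small, genes, "diploid")
        peaks = merge_close_peaks(reproducible_peaks(reps))
        L = cfg_small.chrom_len

        def mirror_gene(g):
            strand = "-" if g.strand == "+" else "+"
            start, end = L - g.end, L - g.start
            tss = start if strand == "+" else end - 1
            tts = end - 1 if strand == "+" else start
            atg = L - 1 - g.atg
            return GeneModel(g.gene_id, g.chrom, start, end, strand, tss, tts,
                             atg, exons=[(start, end)], biotype=g.biotype)

        mirrored_peaks = [Interval(p.chrom, L - p.end, L - p.start, p.name)
                          for p in peaks]
        counts = lambda anns: pd.Series([a.region_class for a in anns]).value_counts()
        a = counts(annotate_peaks(peaks, genes))
        b = counts(annotate_peaks(mirrored_peaks, [mirror_gene(g) for g in genes]))
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_unknown_contig_raises(self):
        with pytest.raises(ValueError, match="contig"):
            annotate_peaks([Interval("chrX", 0, 100)], [_gene()])


class TestTssDistanceCdf:
    def _ann(self, dists):
        return [AnnotatedPeak(Interval("c", 0, 1), "intergenic", None, d)
                for d in dists]

    def test_counting(self):
        cdf = tss_distance_cdf(self._ann([1000, 2000, 50_000, 200_000]))
        assert cdf[3000] == 0.5 and cdf[100_000] == 0.75

    def test_all_at_tss(self):
        cdf = tss_distance_cdf(self._ann([0, 0, 0]))
        assert cdf[3000] == 1.0 and cdf[100_000] == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        cdf = tss_distance_cdf(self._ann(rng.exponential(20_000, 200)),
                               thresholds=[100, 1000, 10_000, 100_000])
        vals = [cdf[t] for t in sorted(cdf)]
        assert vals == sorted(vals)

    def test_hexaploid_tighter_than_diploid_on_preset(self, cfg_small, small_genomes):
        genes_d, genes_h, _ = small_genomes
        out = {}
        for genome, genes in (("diploid", genes_d), ("hexaploid", genes_h)):
            reps, _ = pc.synth.generate_atac(cfg_small, genes, genome)
            peaks = merge_close_peaks(reproducible_peaks(reps))
            anns = annotate_peaks(peaks, genes)
            out[genome] = (tss_distance_cdf(anns)[3000],
                           np.mean([len(a.interval) for a in anns
                                    if a.region_class == "promoter5utr"]))
        assert out["hexaploid"][0] > out["diploid"][0]
        assert out["hexaploid"][1] < out["diploid"][1]


class TestFragmentPeriodicity:
    @pytest.mark.parametrize("period", [10.5, 7.0])
    def test_known_comb_recovered(self, period):
        cfg = pc.GeneratorConfig(seed=13, fragment_period=period)
        lengths = pc.synth.sample_fragment_lengths(cfg, 100_000)
        res = fragment_periodicity(lengths)
        assert res.significant
        assert res.period == pytest.approx(period, abs=0.5)

    def test_flat_histogram_not_significant(self):
        rng = np.random.default_rng(3)
        res = fragment_periodicity(rng.integers(30, 600, size=50_000))
        assert not res.significant and np.isnan(res.period)

    def test_few_fragments_flagged_low_confidence(self):
        with pytest.warns(UserWarning, match="low-confidence"):
            res = fragment_periodicity(np.full(100, 100))
        assert res.low_confidence


class TestGeneAccessibility:
    def _acc(self, peaks, genes):
        return gene_accessibility(annotate_peaks(peaks, genes), genes)

    def test_gene_without_peaks_gets_zeros(self):
        acc = self._acc([], [_gene()])
        assert acc.loc["g1"].sum() == 0

    def test_promoter_totals(self):
        g = _gene()  # atg 10300, promoter [8300, 10300)
        acc = self._acc([Interval("3L", 9000, 9100), Interval("3L", 9500, 9550)], [g])
        assert acc.loc["g1", "n_peaks_promoter5utr"] == 2
        assert acc.loc["g1", "bp_promoter5utr"] == 150

    def test_totals_conserved_under_peak_splitting(self):
        g = _gene()
        whole = self._acc([Interval("3L", 9000, 9200)], [g])
        split = self._acc([Interval("3L", 9000, 9120), Interval("3L", 9120, 9200)], [g])
        assert whole.loc["g1", "bp_promoter5utr"] == split.loc["g1", "bp_promoter5utr"]
        assert split.loc["g1", "n_peaks_promoter5utr"] == 2


class TestDifferentialAccessibility:
    def _table(self, **bp):
        row = {c: 0 for c in ("n_peaks_any", "bp_any", "n_peaks_promoter5utr",
                              "bp_promoter5utr", "n_peaks_cds_intron", "bp_cds_intron",
                              "n_peaks_utr3_downstream", "bp_utr3_downstream")}
        for cls, v in bp.items():
            row[f"bp_{cls}"] = v
            row[f"n_peaks_{cls}"] = 1 if v else 0
        return pd.DataFrame([row], index=pd.Index(["g1"], name="gene_id"))

    def test_presence_absence_difference_flagged(self):
        out = differential_accessibility(self._table(promoter5utr=300), self._table())
        assert out["is_differential"].iloc[0]
        assert out["diff_classes"].iloc[0] == "promoter5utr"

    def test_subthreshold_fold_not_flagged(self):
        out = differential_accessibility(self._table(promoter5utr=100),
                                         self._table(promoter5utr=60))
        assert not out["is_differential"].iloc[0]

    def test_fold_without_absolute_difference_not_flagged(self):
        out = differential_accessibility(self._table(promoter5utr=60),
                                         self._table(promoter5utr=20))
        assert not out["is_differential"].iloc[0]  # 3-fold but only 40 bp

    def test_fold_and_absolute_difference_flagged(self):
        out = differential_accessibility(self._table(cds_intron=300),
                                         self._table(cds_intron=120))
        assert out["is_differential"].iloc[0]
        assert out["diff_classes"].iloc[0] == "cds_intron"

    def test_identical_not_flagged(self):
        out = differential_accessibility(self._table(promoter5utr=200),
                                         self._table(promoter5utr=200))
        assert not out["is_differential"].iloc[0]

    def test_planted_promoter_losses_recovered(self):
        cfg = pc.GeneratorConfig(seed=3, n_genes=150)
        genes_d, genes_h, pairs = pc.synth.generate_gene_models(cfg)
        reps_d, reps_h, truth = pc.synth.generate_atac_pair(cfg, genes_d, genes_h, pairs)
        hex2dip = dict(zip(pairs["hexaploid_gene_id"], pairs["diploid_gene_id"]))
        acc = {}
        for genome, genes, reps in (("d", genes_d, reps_d), ("h", genes_h, reps_h)):
            peaks = merge_close_peaks(reproducible_peaks(reps))
            acc[genome] = gene_accessibility(annotate_peaks(peaks, genes), genes)
        diff = differential_accessibility(acc["d"], acc["h"], id_map=hex2dip)
        m = diff.merge(truth, left_on="gene_id", right_on="diploid_gene_id")
        planted = m[m["atac_diff_true"]]
        nulls = m[~m["atac_diff_true"]]
        assert planted["is_differential"].mean() >= 0.8
        assert nulls["is_differential"].mean() < planted["is_differential"].mean() / 2


class TestDegAtacOverlap:
    def test_disjoint(self):
        out = deg_atac_overlap({"a", "b"}, {"x"})
        assert out["n_overlap"] == 0

    def test_deg_subset_gives_fraction_one(self):
        out = deg_atac_overlap({"a", "b", "c"}, {"a", "b"})
        assert out["fraction_deg_with_diff_peaks"] == 1.0

    def test_counting(self):
        degs = {f"g{i}" for i in range(10)}
        diff = {f"g{i}" for i in range(7)} | {"other"}
        out = deg_atac_overlap(diff, degs)
        assert out["n_overlap"] == 7
        assert out["fraction_deg_with_diff_peaks"] == 0.7
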