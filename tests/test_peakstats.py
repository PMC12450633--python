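from itertools import product

import numpy as np
import pytest
from scipy.stats import chi2

from hepacre.intervals import GeneAnnotation, GenomicInterval, HistoneTrack
from hepacre.peakstats import (
    CATEGORIES,
    category_table,
    chisq_independence,
    gene_coverage,
    histone_match_fraction,
)

from .conftest import random_intervals


def make_peak(chrom, start, end, category, name="p"):
    return GenomicInterval(chrom, start, end, name, peak_category=category)


class TestCategoryTable:
    def test_counts_match_manual_tally(self):
        peaks = {
            "HTN": [make_peak("chr1", i * 10, i * 10 + 5, c, f"h{i}")
                    for i, c in enumerate(
                        ["Promoter", "Promoter", "Distal", "Intronic", "Exonic"])],
            "normal": [make_peak("chr1", i * 10, i * 10 + 5, c, f"n{i}")
                       for i, c in enumerate(
                           ["Distal", "Distal", "Intronic", "Intronic", "Exonic"])],
        }
        table = category_table(peaks)
        assert table.counts.tolist() == [[2, 1, 1, 1], [0, 2, 1, 2]]
        assert np.allclose(table.proportions.sum(axis=1), 1.0)

    def test_single_category_gives_unit_proportion(self):
        table = category_table(
            {"HTN": [make_peak("chr1", 0, 5, "Intronic")]})
        assert table.proportions[0, CATEGORIES.index("Intronic")] == 1.0

    def test_na_peaks_counted_as_unassigned(self):
        table = category_table(
            {"HTN": [make_peak("chr1", 0, 5, "NA"),
                     make_peak("chr1", 10, 15, "Distal")]})
        assert table.unassigned[0] == 1 and table.counts.sum() == 1

    def test_empty_condition_flagged(self):
        with pytest.warns(UserWarning, match="zero categorised"):
            table = category_table({"HTN": []})
        assert table.degenerate_conditions == ["HTN"]
        assert np.isnan(table.proportions[0]).all()


class TestChiSquared:
    def test_closed_form_two_by_two(self):
        result = chisq_independence(np.array([[10, 20], [20, 10]]))
        assert result.statistic == pytest.approx(100 / 15, abs=1e-9)
        assert result.df == 1

    def test_identical_rows_give_zero_statistic(self):
        result = chisq_independence(np.array([[5, 10, 15, 20], [5, 10, 15, 20]]))
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_doubling_counts_doubles_statistic(self):
        base = np.array([[10, 20, 5, 9], [3, 14, 8, 2]])
        s1 = chisq_independence(base).statistic
        s2 = chisq_independence(2 * base).statistic
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_zero_margin_names_degenerate_column(self):
        with pytest.raises(ValueError, match="column 1"):
            chisq_independence(np.array([[5, 0], [7, 0]]))

    def test_agrees_with_pearson_formula(self, rng):
        for _ in range(100):
            counts = rng.integers(1, 200, size=(2, 4))
            result = chisq_independence(counts)
            # independent implementation straight from the definition
            total = counts.sum()
            expected = np.outer(counts.sum(1), counts.sum(0)) / total
            stat = ((counts - expected) ** 2 / expected).sum()
            assert result.statistic == pytest.approx(stat, abs=1e-9)
            assert result.p_value == pytest.approx(chi2.sf(stat, 3), rel=1e-9)


class TestHistoneMatchFraction:
    def test_empty_track_matches_nothing(self):
        peaks = [make_peak("chr1", 0, 100, "Distal")]
        result = histone_match_fraction(peaks, HistoneTrack("H3K4me1", []))
        assert result.matched == 0 and result.matched_fraction == 0.0

    def test_blanket_track_matches_everything(self, rng):
        peaks = random_intervals(rng, 30, chroms=("chr1",), span=1000)
        track = HistoneTrack("H3K27ac", [GenomicInterval("chr1", 0, 10_000)])
        result = histone_match_fraction(peaks, track)
        assert result.matched_fraction == 1.0

    def test_fractions_sum_to_one_and_match_oracle(self, rng):
        peaks = random_intervals(rng, 100)
        track = HistoneTrack("H3K4me3", random_intervals(rng, 60))
        result = histone_match_fraction(peaks, track)
        oracle = sum(
            any(p.chrom == t.chrom and min(p.end, t.end) - max(p.start, t.start) >= 1
                for t in track.intervals)
            for p in peaks)
        assert result.matched == oracle
        assert result.matched_fraction + result.unmatched_fraction == pytest.approx(1)

    def test_empty_peaks_flagged(self):
        with pytest.warns(UserWarning, match="empty peak set"):
            result = histone_match_fraction([], HistoneTrack("H3K4me1", []))
        assert np.isnan(result.matched_fraction)


class TestGeneCoverage:
    def test_gene_with_all_four_categories_lands_in_quad_region(self):
        genes = [GeneAnnotation("G1", "chr1", 50_000, "+")]
        peaks = [make_peak("chr1", 40_000 + i * 1000, 40_500 + i * 1000, c, f"p{i}")
                 for i, c in enumerate(CATEGORIES)]
        cov = gene_coverage(peaks, genes)
        assert cov.genes_all_categories == {"G1"}
        assert cov.venn["&".join(CATEGORIES)] == 1

    def test_no_overlap_gives_empty_sets(self):
        genes = [GeneAnnotation("G1", "chr2", 1_000_000, "+")]
        peaks = [make_peak("chr1", 0, 500, "Distal")]
        cov = gene_coverage(peaks, genes)
        assert all(not s for s in cov.gene_sets.values())

    def test_requires_annotation(self):
        with pytest.raises(ValueError, match="non-empty"):
            gene_coverage([], [])

    def test_venn_matches_powerset_oracle(self, rng):
        genes = [GeneAnnotation(f"G{i}", "chr1", int(rng.integers(0, 500_000)), "+")
                 for i in range(50)]
        peaks = [
            make_peak("chr1", s := int(rng.integers(0, 500_000)), s + 400,
                      str(rng.choice(CATEGORIES)), f"p{i}")
            for i in range(120)
        ]
        cov = gene_coverage(peaks, genes, gene_window_bp=10_000)
        # oracle: direct double loop then exhaustive region enumeration
        sets = {c: set() for c in CATEGORIES}
        for p in peaks:
            for g in genes:
                lo, hi = max(0, g.tss - 10_000), g.tss + 10_000
                if min(hi, p.end) - max(lo, p.start) >= 1:
                    sets[p.peak_category].add(g.gene)
        assert cov.gene_sets == sets
        for mask in product([0, 1], repeat=4):
            if not any(mask):
                continue
            inside = set.intersection(
                *(sets[c] for c, m in zip(CATEGORIES, mask) if m))
            for c, m in zip(CATEGORIES, mask):
                if not m:
                    inside -= sets[c]
            key = "&".join(c for c, m in zip(CATEGORIES, mask) if m)
            assert cov.venn[key] == len(inside)
        union = set().union(*sets.values())
        assert sum(cov.venn.values()) == len(union)
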