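"""Peak-category composition statistics and gene-coverage accounting.

Covers the descriptive comparisons made between disease and normal
accessible-chromatin peak sets: per-category counts/proportions with a
Pearson chi-squared test of independence, the fraction of peaks matched by
a histone track, and which genes are covered by peaks of each positional
category (Venn over the four categories, maximum peaks per gene).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .intervals import GeneAnnotation, GenomicInterval, HistoneTrack, OverlapIndex
from .venn import venn_counts

CATEGORIES = ("Promoter", "Distal", "Exonic", "Intronic")


@dataclasses.dataclass
class CategoryTable:
    """Per-condition counts of the four peak categories.

    Peaks with category "NA" are tallied under ``unassigned`` and excluded
    from both proportions and the chi-squared test.
    """

    conditions: list[str]
    counts: np.ndarray  # len(conditions) x 4
    unassigned: np.ndarray

    @property
    def proportions(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = self.counts / totals
        return props

    @property
    def degenerate_conditions(self) -> list[str]:
        return [c for c, t in zip(self.conditions, self.counts.sum(axis=1)) if t == 0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=self.conditions, columns=CATEGORIES)
        frame["unassigned"] = self.unassigned
        return frame


@dataclasses.dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclasses.dataclass
class HistoneMatchResult:
    mark: str
    n_peaks: int
    matched: int
    matched_fraction: float
    unmatched_fraction: float


@dataclasses.dataclass
class GeneCoverage:
    """Per-category gene sets and per-gene peak counts within TSS windows."""

    gene_sets: dict[str, set[str]]         # category -> genes with >= 1 peak
    counts: pd.DataFrame                   # genes x categories, peak counts
    venn: dict[str, int]                   # exclusive regions over the 4 sets
    max_peaks_per_category: dict[str, int]
    genes_all_categories: set[str]


def category_table(
    peaks_by_condition: Mapping[str, Sequence[GenomicInterval]]
) -> CategoryTable:
    conditions = list(peaks_by_condition)
    counts = np.zeros((len(conditions), len(CATEGORIES)), dtype=int)
    unassigned = np.zeros(len(conditions), dtype=int)
    cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
    for row, cond in enumerate(conditions):
        for peak in peaks_by_condition[cond]:
            if peak.peak_category == "NA":
                unassigned[row] += 1
            else:
                counts[row, cat_idx[peak.peak_category]] += 1
    table = CategoryTable(conditions, counts, unassigned)
    if table.degenerate_conditions:
        warnings.warn(
            f"conditions with zero categorised peaks: {table.degenerate_conditions}",
            stacklevel=2,
        )
    return table


def chisq_independence(table: CategoryTable | np.ndarray) -> ChiSquareResult:
    """Pearson chi-squared test of category x condition independence.

    No continuity correction; df = (rows - 1)(cols - 1). A zero row or
    column margin is an error naming the degenerate margin.
    """
    if isinstance(table, CategoryTable):
        counts = table.counts
        row_names, col_names = table.conditions, list(CATEGORIES)
    else:
        counts = np.asarray(table)
        row_names = [f"row {i}" for i in range(counts.shape[0])]
        col_names = [f"column {j}" for j in range(counts.shape[1])]
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    for i, total in enumerate(counts.sum(axis=1)):
        if total == 0:
            raise ValueError(f"zero margin: {row_names[i]} has no counts")
    for j, total in enumerate(counts.sum(axis=0)):
        if total == 0:
            raise ValueError(f"zero margin: {col_names[j]} has no counts")
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def histone_match_fraction(peaks: Sequence[GenomicInterval], track: HistoneTrack,
                           min_bp: int = 1) -> HistoneMatchResult:
    """Fraction of peaks overlapped by >= 1 interval of the histone track."""
    if not peaks:
        warnings.warn("empty peak set: match fractions undefined", stacklevel=2)
        return HistoneMatchResult(track.mark, 0, 0, float("nan"), float("nan"))
    index = OverlapIndex(track.intervals)
    matched = sum(1 for p in peaks if index.query(p, min_bp=min_bp))
    frac = matched / len(peaks)
    return HistoneMatchResult(track.mark, len(peaks), matched, frac, 1.0 - frac)


def gene_coverage(peaks: Sequence[GenomicInterval],
                  annotation: Sequence[GeneAnnotation],
                  gene_window_bp: int = 50_000) -> GeneCoverage:
    """Assign peaks to TSS-anchored gene windows and summarise per category.

    A gene's region is TSS +/- gene_window_bp (clamped at 0); a peak
    overlapping several gene windows counts for every such gene. Peaks with
    category "NA" are ignored.
    """
    if not annotation:
        raise ValueError("gene annotation must be non-empty")
    windows = [
        GenomicInterval(g.chrom, max(0, g.tss - gene_window_bp),
                        g.tss + gene_window_bp, g.gene)
        for g in annotation
    ]
    index = OverlapIndex(windows)
    counts: dict[str, dict[str, int]] = {}
    for peak in peaks:
        if peak.peak_category == "NA":
            continue
        for i in index.query(peak):
            gene = windows[i].name
            row = counts.setdefault(gene, {c: 0 for c in CATEGORIES})
            row[peak.peak_category] += 1

    frame = pd.DataFrame.from_dict(counts, orient="index").reindex(
        columns=CATEGORIES, fill_value=0
    ).sort_index()
    gene_sets = {
        c: (set(frame.index[frame[c] > 0]) if not frame.empty else set())
        for c in CATEGORIES
    }
    maxima = {
        c: (int(frame[c].max()) if not frame.empty else 0) for c in CATEGORIES
    }
    all_four = (set.intersection(*gene_sets.values()) if all(gene_sets.values())
                else set())
    return GeneCoverage(gene_sets, frame, venn_counts(gene_sets), maxima, all_four)
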