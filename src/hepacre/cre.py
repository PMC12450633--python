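"""Promoter/enhancer calling from accessible peaks + histone evidence.

Classification rules:

* promoter — an accessible peak positionally categorised "Promoter" that
  overlaps at least one H3K4me3 interval;
* enhancer — a peak of any *other* category (Distal/Exonic/Intronic) that
  overlaps at least one H3K4me1 interval AND at least one H3K27ac interval.

The category requirement makes the two classes disjoint by construction.
Gene assignment here is a positional fallback (nearest TSS); authoritative
enhancer-to-gene links come from the evidence tables consumed by
:mod:`hepacre.grn`.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import pandas as pd

from .intervals import GeneAnnotation, GenomicInterval, HistoneTrack, OverlapIndex


@dataclasses.dataclass
class CRECall:
    """An accessible peak promoted to promoter/enhancer status.

    ``distance_to_tss`` is signed and strand-aware: measured from the TSS to
    the peak midpoint, negative when the peak lies upstream of the TSS on the
    gene's strand. ``gene`` is None when unassigned.
    """

    interval: GenomicInterval
    cre_class: str  # "promoter" | "enhancer"
    evidence: frozenset[str]
    gene: str | None = None
    distance_to_tss: int | None = None

    def __post_init__(self):
        if self.cre_class == "promoter":
            if "H3K4me3" not in self.evidence:
                raise ValueError("promoter call requires H3K4me3 evidence")
            if self.interval.peak_category != "Promoter":
                raise ValueError("promoter call requires Promoter-category peak")
        elif self.cre_class == "enhancer":
            if not {"H3K4me1", "H3K27ac"} <= set(self.evidence):
                raise ValueError("enhancer call requires H3K4me1 and H3K27ac")
            if self.interval.peak_category == "Promoter":
                raise ValueError("enhancer call forbidden for Promoter category")
        else:
            raise ValueError(f"unknown cre_class {self.cre_class!r}")

    @property
    def cre_id(self) -> str:
        return self.interval.name


def _require_mark(track: HistoneTrack, mark: str) -> None:
    if track.mark != mark:
        raise ValueError(f"expected a {mark} track, got {track.mark}")


def call_promoters(peaks: Sequence[GenomicInterval], h3k4me3: HistoneTrack,
                   min_bp: int = 1) -> list[CRECall]:
    """Promoter-category peaks with >= 1 qualifying H3K4me3 overlap."""
    _require_mark(h3k4me3, "H3K4me3")
    index = OverlapIndex(h3k4me3.intervals)
    calls = []
    for peak in peaks:
        if peak.peak_category != "Promoter":
            continue
        if index.query(peak, min_bp=min_bp):
            calls.append(CRECall(peak, "promoter", frozenset({"H3K4me3"})))
    return calls


def call_enhancers(peaks: Sequence[GenomicInterval], h3k4me1: HistoneTrack,
                   h3k27ac: HistoneTrack, min_bp: int = 1) -> list[CRECall]:
    """Non-Promoter-category peaks overlapping both H3K4me1 and H3K27ac."""
    _require_mark(h3k4me1, "H3K4me1")
    _require_mark(h3k27ac, "H3K27ac")
    idx1 = OverlapIndex(h3k4me1.intervals)
    idx2 = OverlapIndex(h3k27ac.intervals)
    calls = []
    for peak in peaks:
        if peak.peak_category == "Promoter":
            continue
        if idx1.query(peak, min_bp=min_bp) and idx2.query(peak, min_bp=min_bp):
            calls.append(CRECall(peak, "enhancer",
                                 frozenset({"H3K4me1", "H3K27ac"})))
    return calls


def _signed_distance(tss: int, strand: str, midpoint: int) -> int:
    # negative = peak upstream of the TSS on the gene's strand
    return midpoint - tss if strand == "+" else tss - midpoint


def assign_gene(call: CRECall, annotation: Sequence[GeneAnnotation],
                promoter_window_bp: int = 2000,
                enhancer_max_distance_bp: int = 100_000) -> CRECall:
    """Assign the call to a gene by TSS proximity.

    Promoters: candidate genes are those whose TSS lies inside the peak or
    within promoter_window_bp of its boundaries; the nearest TSS (by absolute
    distance to the peak midpoint) wins, ties by lexicographically smaller
    gene symbol. Enhancers: nearest TSS within enhancer_max_distance_bp of
    the midpoint, else unassigned.
    """
    if not annotation:
        raise ValueError("gene annotation must be non-empty")
    peak = call.interval
    mid = peak.midpoint
    best: tuple[int, str] | None = None
    best_gene: GeneAnnotation | None = None
    for g in annotation:
        if g.chrom != peak.chrom:
            continue
        if call.cre_class == "promoter":
            if not (peak.start - promoter_window_bp <= g.tss
                    < peak.end + promoter_window_bp):
                continue
        else:
            if abs(g.tss - mid) > enhancer_max_distance_bp:
                continue
        key = (abs(g.tss - mid), g.gene)
        if best is None or key < best:
            best, best_gene = key, g
    if best_gene is None:
        return dataclasses.replace(call, gene=None, distance_to_tss=None)
    return dataclasses.replace(
        call,
        gene=best_gene.gene,
        distance_to_tss=_signed_distance(best_gene.tss, best_gene.strand, mid),
    )


def assign_genes(calls: Sequence[CRECall], annotation: Sequence[GeneAnnotation],
                 promoter_window_bp: int = 2000,
                 enhancer_max_distance_bp: int = 100_000) -> list[CRECall]:
    return [assign_gene(c, annotation, promoter_window_bp,
                        enhancer_max_distance_bp) for c in calls]


# ---------------------------------------------------------------------------
# I/O: CRE call table (BED-like TSV with extra columns)
# ---------------------------------------------------------------------------

CRE_COLUMNS = ("chrom", "start", "end", "name", "peak_category", "cre_class",
               "evidence", "gene", "distance_to_tss")


def write_cre_calls(calls: Sequence[CRECall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CRE_COLUMNS) + "\n")
        for c in calls:
            iv = c.interval
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end), iv.name, iv.peak_category,
                c.cre_class, ",".join(sorted(c.evidence)),
                c.gene if c.gene is not None else ".",
                str(c.distance_to_tss) if c.distance_to_tss is not None else ".",
            ]) + "\n")


def read_cre_calls(path) -> list[CRECall]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CRE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: CRE table missing columns {missing}")
    calls = []
    for row in frame.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.name,
                             peak_category=row.peak_category)
        calls.append(CRECall(
            iv, row.cre_class, frozenset(row.evidence.split(",")),
            gene=None if row.gene == "." else row.gene,
            distance_to_tss=None if row.distance_to_tss == "."
            else int(row.distance_to_tss),
        ))
    return calls
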