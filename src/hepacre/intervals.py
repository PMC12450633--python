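"""Genomic interval model, BED/narrowPeak I/O and the overlap engine.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.
Accessible-chromatin and histone ChIP-seq peaks are unstranded, so strand
never enters overlap arithmetic; gene strand matters only for the sign of
TSS-relative distances (see :mod:`hepacre.cre`).

Chromosome names are matched by exact string equality ("chr1" != "1");
:func:`normalize_chrom_names` is provided for inputs that mix styles.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

from intervaltree import IntervalTree

PEAK_CATEGORIES = ("Promoter", "Distal", "Exonic", "Intronic", "NA")
HISTONE_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac")


class BedParseError(ValueError):
    """Raised when a BED/narrowPeak line cannot be parsed; names the line."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}: line {lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span, the unit of all overlap arithmetic.

    ``peak_category`` carries the accessible-peak positional class
    (Promoter/Distal/Exonic/Intronic) when known, "NA" otherwise.
    ``summit_offset`` is the narrowPeak point-source offset from ``start``
    (-1 when absent).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    peak_category: str = "NA"
    summit_offset: int = -1

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.peak_category not in PEAK_CATEGORIES:
            raise ValueError(
                f"peak_category {self.peak_category!r} not in {PEAK_CATEGORIES}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass
class HistoneTrack:
    """A named histone-modification peak set (H3K4me1, H3K4me3 or H3K27ac)."""

    mark: str
    intervals: list[GenomicInterval]

    def __post_init__(self):
        if self.mark not in HISTONE_MARKS:
            raise ValueError(f"mark {self.mark!r} not in {HISTONE_MARKS}")


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    """One gene's TSS anchor: symbol, chromosome, 0-based TSS and strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_coords(path, lineno, fields):
    if len(fields) < 3:
        raise BedParseError(path, lineno, f"expected >= 3 fields, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(path, lineno, f"non-integer coordinate: {exc}") from exc
    if end <= start:
        raise BedParseError(path, lineno, f"end <= start ([{start}, {end}))")
    return fields[0], start, end


def read_bed(path, category_column: int | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6(+) into intervals.

    BED coordinates are already 0-based half-open and are taken as written.
    ``category_column`` is a 0-based column index holding the peak category
    (the writer puts it in column 6, i.e. index 6); unknown category values
    raise :class:`BedParseError`.
    """
    out = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _parse_coords(path, lineno, fields)
        name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{len(out)}"
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise BedParseError(path, lineno, f"bad score {fields[4]!r}") from exc
        category = "NA"
        if category_column is not None:
            if len(fields) <= category_column:
                raise BedParseError(
                    path, lineno, f"no category column {category_column}"
                )
            category = fields[category_column]
            if category not in PEAK_CATEGORIES:
                raise BedParseError(
                    path, lineno,
                    f"unknown peak category {category!r} (allowed: {PEAK_CATEGORIES})",
                )
        out.append(GenomicInterval(chrom, start, end, name, score, category))
    return out


def read_narrowpeak(path) -> list[GenomicInterval]:
    """Read ENCODE narrowPeak (10 columns; column 10 is the summit offset)."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise BedParseError(
                path, lineno, f"narrowPeak requires 10 fields, got {len(fields)}"
            )
        chrom, start, end = _parse_coords(path, lineno, fields)
        name = fields[3] if fields[3] != "." else f"peak_{len(out)}"
        score = float(fields[4]) if fields[4] not in (".", "") else None
        try:
            summit = int(fields[9])
        except ValueError as exc:
            raise BedParseError(path, lineno, f"bad summit {fields[9]!r}") from exc
        out.append(GenomicInterval(chrom, start, end, name, score,
                                   summit_offset=summit))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path,
              include_category: bool = False) -> None:
    """Write BED6 (+ optional category column 7).

    Round-trip contract: ``read_bed(write_bed(x))`` reproduces
    chrom/start/end/name field-by-field.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else f"{iv.score:g}"
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, score, "."]
            if include_category:
                fields.append(iv.peak_category)
            fh.write("\t".join(fields) + "\n")


def write_narrowpeak(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end), iv.name, score, ".",
                "0", "-1", "-1", str(iv.summit_offset),
            ]) + "\n")


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read a gene/chrom/tss/strand TSV (header required); symbols must be unique."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("gene", "chrom", "tss", "strand"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            gene = fields[idx["gene"]]
            if gene in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            genes.append(GeneAnnotation(
                gene, fields[idx["chrom"]], int(fields[idx["tss"]]),
                fields[idx["strand"]]))
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def normalize_chrom_names(intervals: Sequence[GenomicInterval],
                          style: str = "ucsc") -> list[GenomicInterval]:
    """Coerce chromosome names to one style: "ucsc" ("chr1") or "ensembl" ("1")."""
    if style not in ("ucsc", "ensembl"):
        raise ValueError("style must be 'ucsc' or 'ensembl'")
    out = []
    for iv in intervals:
        chrom = iv.chrom
        if style == "ucsc" and not chrom.startswith("chr"):
            chrom = "chr" + chrom
        elif style == "ensembl" and chrom.startswith("chr"):
            chrom = chrom[3:]
        out.append(dataclasses.replace(iv, chrom=chrom))
    return out


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------

def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff a and b share >= min_bp bases on the same chromosome.

    Half-open convention: [0, 100) and [100, 200) do not overlap.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


class OverlapIndex:
    """Per-chromosome interval tree over a subject set, for repeated queries."""

    def __init__(self, subjects: Sequence[GenomicInterval]):
        self.subjects = list(subjects)
        self._trees: dict[str, IntervalTree] = {}
        for i, iv in enumerate(self.subjects):
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, i)

    def query(self, q: GenomicInterval, min_bp: int = 1) -> list[int]:
        """Indices of subjects overlapping q by >= min_bp, in subject order."""
        if min_bp < 1:
            raise ValueError(f"min_bp must be >= 1, got {min_bp}")
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        hits = [
            hit.data for hit in tree.overlap(q.start, q.end)
            if min(hit.end, q.end) - max(hit.begin, q.start) >= min_bp
        ]
        return sorted(hits)


def match_any(queries: Sequence[GenomicInterval],
              subjects: Sequence[GenomicInterval],
              min_bp: int = 1) -> tuple[list[bool], list[list[str]]]:
    """For each query, whether any subject overlaps it, plus the matched names.

    Returns a boolean vector in query order and, per query, the names of all
    matching subjects (in subject input order).
    """
    index = OverlapIndex(subjects)
    flags: list[bool] = []
    matched: list[list[str]] = []
    for q in queries:
        hits = index.query(q, min_bp=min_bp)
        flags.append(bool(hits))
        matched.append([subjects[i].name for i in hits])
    return flags, matched
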