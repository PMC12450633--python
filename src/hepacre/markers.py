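"""Condition marker genes: condition-upregulated ∩ pathway gene sets.

The disease-skewed hepatocyte subtype's disease-vs-normal DEG contrast is
filtered for upregulation, then intersected with externally supplied pathway
gene sets (e.g. GO biological processes such as fatty acid metabolic process,
GO:0006631). Pathway membership is an input, not computed: enrichment itself
is upstream of this package.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import pandas as pd

from .venn import venn_counts


@dataclasses.dataclass
class PathwayGeneSet:
    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id} has no genes")
        self.genes = frozenset(self.genes)


def read_gmt(path) -> list[PathwayGeneSet]:
    """Read GMT: pathway_id <tab> description <tab> gene1 <tab> gene2 ..."""
    out = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs >= 3 fields")
            pid = fields[0]
            if pid in seen:
                raise ValueError(f"{path}: duplicate pathway id {pid!r}")
            seen.add(pid)
            out.append(PathwayGeneSet(pid, fields[1],
                                      frozenset(g for g in fields[2:] if g)))
    return out


def upregulated_in_condition(degs: pd.DataFrame, contrast: str,
                             fc_min: float = 0.0,
                             p_max: float = 0.05) -> frozenset[str]:
    """Genes with avg_log2FC > fc_min and p_val < p_max in the named contrast."""
    if "contrast" not in degs.columns:
        raise ValueError("DEG table has no 'contrast' column")
    sub = degs[degs["contrast"] == contrast]
    if sub.empty:
        raise KeyError(f"contrast {contrast!r} absent from DEG table")
    passing = sub[(sub["avg_log2FC"] > fc_min) & (sub["p_val"] < p_max)]
    return frozenset(passing["gene"])


def intersect_with_pathways(
    upregulated: frozenset[str] | set[str],
    pathways: Sequence[PathwayGeneSet],
    uppercase: bool = False,
) -> tuple[frozenset[str], dict[str, int]]:
    """Markers = upregulated ∩ (union of pathway gene sets), plus Venn counts.

    Matching is case-sensitive exact match unless ``uppercase`` normalises
    both sides. Venn counts cover the upregulated set and each pathway set
    as separate circles.
    """
    def norm(genes):
        return {g.upper() for g in genes} if uppercase else set(genes)

    up = norm(upregulated)
    union = set()
    named = {"upregulated": up}
    for pw in pathways:
        genes = norm(pw.genes)
        union |= genes
        named[pw.pathway_id] = genes
    markers = frozenset(up & union)
    return markers, venn_counts(named)
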