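"""Motif enrichment and evidence-filtered gene-regulatory networks.

Two networks are built for the disease-skewed hepatocyte subtype:

* promoter network — TF -> promoter -> gene edges where the gene is
  condition-upregulated, owns a histone-supported promoter call, and the
  TF's motif occurs in that promoter's peak;
* enhancer network — inferred enhancer-gene links (SCENIC+-style) kept only
  when a curated annotation (GeneHancer-style) supports the same gene at
  overlapping coordinates AND the enhancer overlaps a histone-supported
  enhancer call (the triple-evidence filter).

Motif over-representation in a CRE set versus a background peak set is
scored by the upper-tail hypergeometric probability with Benjamini-Hochberg
correction across motifs.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cre import CRECall
from .intervals import GenomicInterval, OverlapIndex


@dataclasses.dataclass(frozen=True)
class EnhancerLink:
    """One enhancer-gene link from an inferred or curated source."""

    enhancer: GenomicInterval
    gene: str
    tf: str | None = None
    source: str = "inferred"
    score: float | None = None

    def __post_init__(self):
        if self.source not in ("inferred", "curated"):
            raise ValueError(f"source must be inferred/curated, got {self.source!r}")


@dataclasses.dataclass(frozen=True)
class RegulatoryEdge:
    """TF -> CRE -> gene triple with its supporting evidence sources."""

    tf: str
    cre_id: str
    gene: str
    cre_class: str
    evidence_sources: frozenset[str]

    @property
    def is_self_loop(self) -> bool:
        return self.tf == self.gene


@dataclasses.dataclass
class EnhancerNetworkResult:
    edges: list[RegulatoryEdge]
    venn_pairs: dict[str, int]    # over enhancer-gene link evidence combos
    venn_regions: dict[str, int]  # over unique enhancer coordinates


# ---------------------------------------------------------------------------
# Motif occurrences and enrichment
# ---------------------------------------------------------------------------

def read_motif_occurrences(path) -> pd.DataFrame:
    occ = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("peak_id", "motif"):
        if col not in occ.columns:
            raise ValueError(f"{path}: motif table missing column {col!r}")
    if occ.duplicated(["peak_id", "motif"]).any():
        raise ValueError(f"{path}: duplicate (peak_id, motif) pairs")
    return occ


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (monotone in p-rank, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def motif_enrichment(target_peaks: set[str], background_peaks: set[str],
                     occurrences: pd.DataFrame) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of target peaks vs background.

    For a motif occurring in K of the N background peaks and k of the n
    target peaks, p = P(X >= k) under Hypergeometric(N, K, n); q is the BH
    adjustment across motifs. Fold = (k/n) / (K/N). Occurrences outside the
    background are ignored.
    """
    target = set(target_peaks)
    background = set(background_peaks)
    if not target <= background:
        raise ValueError("target peak set must be a subset of the background")
    occ = occurrences[occurrences["peak_id"].isin(background)]
    N, n = len(background), len(target)
    rows = []
    for motif, group in occ.groupby("motif", sort=True):
        peaks_with = set(group["peak_id"])
        K = len(peaks_with)
        k = len(peaks_with & target)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
        rows.append((motif, k, n, K, N, fold, p))
    result = pd.DataFrame(
        rows, columns=["motif", "k_target", "n_target", "K_background",
                       "N_background", "fold", "p_value"],
    )
    result["q_value"] = benjamini_hochberg(result["p_value"].to_numpy())
    return result.sort_values(["p_value", "motif"], kind="mergesort",
                              ignore_index=True)


# ---------------------------------------------------------------------------
# Promoter network
# ---------------------------------------------------------------------------

def build_promoter_network(upregulated: set[str],
                           promoter_calls: Sequence[CRECall],
                           occurrences: pd.DataFrame,
                           tf_universe: set[str]) -> list[RegulatoryEdge]:
    """TF -> promoter -> gene edges for condition-upregulated genes.

    An edge is emitted iff the gene is upregulated, owns a promoter call,
    the TF's motif occurs in that promoter's peak, and the TF belongs to
    tf_universe. Self-loops (tf == gene) are retained; callers can flag
    them via :attr:`RegulatoryEdge.is_self_loop`.
    """
    motifs_by_peak: dict[str, list[str]] = {
        peak: sorted(group["motif"]) for peak, group in
        occurrences.groupby("peak_id", sort=True)
    }
    edges = []
    for call in promoter_calls:
        if call.cre_class != "promoter" or call.gene is None:
            continue
        if call.gene not in upregulated:
            continue
        for tf in motifs_by_peak.get(call.cre_id, []):
            if tf in tf_universe:
                edges.append(RegulatoryEdge(
                    tf, call.cre_id, call.gene, "promoter",
                    frozenset({"motif", "histone"})))
    return edges


# ---------------------------------------------------------------------------
# Enhancer network: triple-evidence filter
# ---------------------------------------------------------------------------

def _coord_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def build_enhancer_network(inferred: Sequence[EnhancerLink],
                           curated: Sequence[EnhancerLink],
                           enhancer_calls: Sequence[CRECall],
                           min_bp: int = 1,
                           require_gene_match: bool = True
                           ) -> EnhancerNetworkResult:
    """Filter inferred links by curated and histone support.

    An inferred link survives iff (a) some curated link overlaps its
    enhancer coordinates by >= min_bp and (when ``require_gene_match``)
    targets the same gene, and (b) its enhancer overlaps a histone-supported
    enhancer call. Venn counts are reported both per enhancer-gene link and
    per unique enhancer region.
    """
    curated_index = OverlapIndex([ln.enhancer for ln in curated])
    call_index = OverlapIndex([c.interval for c in enhancer_calls])

    edges = []
    link_flags = []
    for link in inferred:
        cur_hits = curated_index.query(link.enhancer, min_bp=min_bp)
        if require_gene_match:
            cur_ok = any(curated[i].gene == link.gene for i in cur_hits)
        else:
            cur_ok = bool(cur_hits)
        hist_ok = bool(call_index.query(link.enhancer, min_bp=min_bp))
        link_flags.append((link, cur_ok, hist_ok))
        if cur_ok and hist_ok:
            sources = frozenset({"inferred", "curated", "histone"})
            edges.append(RegulatoryEdge(
                link.tf if link.tf else "unknown",
                _coord_id(link.enhancer), link.gene, "enhancer", sources))

    def combo(cur_ok, hist_ok):
        parts = ["inferred"]
        if cur_ok:
            parts.append("curated")
        if hist_ok:
            parts.append("histone")
        return "&".join(parts)

    venn_pairs: dict[str, int] = {
        "inferred": 0, "inferred&curated": 0, "inferred&histone": 0,
        "inferred&curated&histone": 0,
    }
    for _, cur_ok, hist_ok in link_flags:
        venn_pairs[combo(cur_ok, hist_ok)] += 1

    regions: dict[str, tuple[bool, bool]] = {}
    for link, cur_ok, hist_ok in link_flags:
        cid = _coord_id(link.enhancer)
        prev = regions.get(cid, (False, False))
        regions[cid] = (prev[0] or cur_ok, prev[1] or hist_ok)
    venn_regions: dict[str, int] = {
        "inferred": 0, "inferred&curated": 0, "inferred&histone": 0,
        "inferred&curated&histone": 0,
    }
    for cur_ok, hist_ok in regions.values():
        venn_regions[combo(cur_ok, hist_ok)] += 1

    return EnhancerNetworkResult(edges, venn_pairs, venn_regions)


# ---------------------------------------------------------------------------
# I/O and graph export
# ---------------------------------------------------------------------------

LINK_COLUMNS = ("chrom", "start", "end", "gene", "tf", "source", "score")


def read_link_table(path) -> list[EnhancerLink]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LINK_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: link table missing columns {missing}")
    links = []
    for i, row in enumerate(frame.itertuples(index=False)):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end),
                             name=f"link_{i}")
        links.append(EnhancerLink(
            iv, row.gene,
            tf=None if row.tf in (".", "", None) or pd.isna(row.tf) else row.tf,
            source=row.source,
            score=None if row.score in (".", "", None) or pd.isna(row.score)
            else float(row.score),
        ))
    return links


def write_link_table(links: Sequence[EnhancerLink], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LINK_COLUMNS) + "\n")
        for ln in links:
            iv = ln.enhancer
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end), ln.gene,
                ln.tf if ln.tf else ".", ln.source,
                f"{ln.score:g}" if ln.score is not None else ".",
            ]) + "\n")


def edges_to_frame(edges: Sequence[RegulatoryEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.tf, e.cre_id, e.cre_class, e.gene,
          ",".join(sorted(e.evidence_sources)), e.is_self_loop)
         for e in edges],
        columns=["tf", "cre_id", "cre_class", "gene", "evidence_sources",
                 "self_loop"],
    )


def write_edges(edges: Sequence[RegulatoryEdge], path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False)


def to_networkx(edges: Sequence[RegulatoryEdge]):
    """Directed TF -> gene graph; CREs live on the edges as attributes."""
    import networkx as nx

    graph = nx.MultiDiGraph()
    for e in edges:
        graph.add_node(e.tf, kind="tf")
        graph.add_node(e.gene, kind="gene")
        graph.add_edge(e.tf, e.gene, cre_id=e.cre_id, cre_class=e.cre_class,
                       evidence=",".join(sorted(e.evidence_sources)))
    return graph


def write_graph_json(edges: Sequence[RegulatoryEdge], path) -> None:
    """Deterministic JSON export: sorted node and edge lists."""
    nodes = sorted({e.tf for e in edges} | {e.gene for e in edges})
    kinds = {n: "gene" for n in nodes}
    for e in edges:
        kinds[e.tf] = "tf"  # a self-regulating gene is exported as tf
    payload = {
        "nodes": [{"id": n, "kind": kinds[n]} for n in nodes],
        "edges": sorted(
            ({"tf": e.tf, "gene": e.gene, "cre_id": e.cre_id,
              "cre_class": e.cre_class,
              "evidence": sorted(e.evidence_sources)} for e in edges),
            key=lambda d: (d["tf"], d["gene"], d["cre_id"]),
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
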