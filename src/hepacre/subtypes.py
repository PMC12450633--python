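"""Hepatocyte cluster consolidation by top-k upregulated-gene Jaccard similarity.

Each annotated cluster is reduced to its top-k upregulated genes
(avg_log2FC > fc_min, p_val < p_max, sorted by avg_log2FC), pairwise Jaccard
indices J = |a ∩ b| / |a ∪ b| are computed, and clusters are merged into
subtypes by complete-linkage agglomerative clustering on distance 1 - J.
Clusters with zero similarity to every other cluster are excluded before
clustering (they are not the same cell type), mirroring the treatment of a
cholangiocyte cluster mis-annotated as hepatocytes.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEG_COLUMNS = ("gene", "cluster", "avg_log2FC", "p_val")


@dataclasses.dataclass
class ClusterGeneSet:
    """A cluster's top-k upregulated genes, in descending avg_log2FC order."""

    cluster: str
    genes: tuple[str, ...]

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclasses.dataclass
class JaccardMatrix:
    clusters: list[str]
    values: np.ndarray  # symmetric, entries in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.clusters, columns=self.clusters)


@dataclasses.dataclass
class SubtypeAssignment:
    """cluster -> "Subtype_1", "Subtype_2", ... or "excluded"."""

    mapping: dict[str, str]

    def members(self, label: str) -> list[str]:
        return sorted(c for c, lab in self.mapping.items() if lab == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": list(self.mapping), "subtype": list(self.mapping.values())}
        )


def read_deg_table(path) -> pd.DataFrame:
    degs = pd.read_csv(path, sep="\t", dtype={"gene": str, "cluster": str})
    missing = [c for c in DEG_COLUMNS if c not in degs.columns]
    if missing:
        raise ValueError(f"{path}: DEG table missing columns {missing}")
    return degs


def top_upregulated(degs: pd.DataFrame, cluster: str, k: int = 20,
                    fc_min: float = 0.0, p_max: float = 0.05) -> ClusterGeneSet:
    """Top-k genes of a cluster with avg_log2FC > fc_min and p_val < p_max.

    Sorted by avg_log2FC descending, ties broken by gene symbol ascending,
    truncated to k; if fewer than k genes pass the filters, all survivors
    are returned.
    """
    cluster = str(cluster)
    sub = degs[degs["cluster"].astype(str) == cluster]
    if sub.empty:
        raise KeyError(f"cluster {cluster!r} absent from DEG table")
    passing = sub[(sub["avg_log2FC"] > fc_min) & (sub["p_val"] < p_max)]
    ordered = passing.sort_values(
        ["avg_log2FC", "gene"], ascending=[False, True], kind="mergesort"
    )
    return ClusterGeneSet(cluster, tuple(ordered["gene"].head(k)))


def jaccard(a, b) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|; two empty sets give 0 with a warning."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def jaccard_matrix(gene_sets: Sequence[ClusterGeneSet]) -> JaccardMatrix:
    if len(gene_sets) < 2:
        raise ValueError("jaccard_matrix requires at least 2 clusters")
    n = len(gene_sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = jaccard(
                gene_sets[i].gene_set, gene_sets[j].gene_set
            )
    return JaccardMatrix([gs.cluster for gs in gene_sets], values)


def _validate_matrix(matrix: JaccardMatrix) -> np.ndarray:
    values = np.asarray(matrix.values, dtype=float)
    n = len(matrix.clusters)
    if values.shape != (n, n):
        raise ValueError("matrix shape does not match cluster list")
    if not np.allclose(values, values.T):
        raise ValueError("similarity matrix must be symmetric")
    if values.min() < -1e-12 or values.max() > 1 + 1e-12:
        raise ValueError("similarities must lie in [0, 1]")
    return values


def merge_subtypes(matrix: JaccardMatrix, n_subtypes: int = 2) -> SubtypeAssignment:
    """Cut the complete-linkage tree on 1 - J into n_subtypes groups.

    Clusters whose off-diagonal similarity row is all zero are labelled
    "excluded" before clustering. Subtype labels are assigned by descending
    group size (ties by smallest member cluster id), so "Subtype_1" is
    always the largest group.
    """
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    values = _validate_matrix(matrix)
    n = len(matrix.clusters)
    off = values - np.diag(np.diag(values))
    excluded = [i for i in range(n) if off[i].max() == 0.0]
    kept = [i for i in range(n) if i not in excluded]
    if not kept:
        raise ValueError("no mergeable structure: all clusters mutually zero-similar")
    if len(kept) < n_subtypes:
        raise ValueError(
            f"only {len(kept)} clusters remain after exclusion; "
            f"cannot form {n_subtypes} subtypes"
        )

    mapping = {matrix.clusters[i]: "excluded" for i in excluded}
    sub = values[np.ix_(kept, kept)]
    if len(kept) == 1:
        groups = np.array([1])
    else:
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        tree = linkage(condensed, method="complete")
        groups = fcluster(tree, t=n_subtypes, criterion="maxclust")

    by_group: dict[int, list[int]] = {}
    for idx, g in zip(kept, groups):
        by_group.setdefault(int(g), []).append(idx)
    ordered = sorted(
        by_group.values(),
        key=lambda members: (-len(members), min(matrix.clusters[i] for i in members)),
    )
    for rank, members in enumerate(ordered, start=1):
        for i in members:
            mapping[matrix.clusters[i]] = f"Subtype_{rank}"
    return SubtypeAssignment({c: mapping[c] for c in matrix.clusters})


def cluster_gene_sets(degs: pd.DataFrame, k: int = 20, fc_min: float = 0.0,
                      p_max: float = 0.05) -> list[ClusterGeneSet]:
    """Top-k sets for every cluster in the table, in sorted cluster order."""
    clusters = sorted(degs["cluster"].astype(str).unique())
    return [top_upregulated(degs, c, k=k, fc_min=fc_min, p_max=p_max)
            for c in clusters]
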