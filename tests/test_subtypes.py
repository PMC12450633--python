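import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hepacre.subtypes import (
    ClusterGeneSet,
    JaccardMatrix,
    cluster_gene_sets,
    jaccard,
    jaccard_matrix,
    merge_subtypes,
    top_upregulated,
)
from hepacre.synthetic import SyntheticConfig, generate_deg_tables

gene_sets_st = st.sets(st.sampled_from([f"g{i}" for i in range(30)]), max_size=20)


def deg_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "cluster", "avg_log2FC", "p_val"])


class TestTopUpregulated:
    def test_filters_and_truncates_against_row_scan(self, rng):
        rows = [(f"g{i}", "C0", float(rng.normal()), float(rng.random()))
                for i in range(200)]
        degs = deg_frame(rows)
        result = top_upregulated(degs, "C0", k=20)
        oracle = sorted(
            [r for r in rows if r[2] > 0 and r[3] < 0.05],
            key=lambda r: (-r[2], r[0]),
        )[:20]
        assert list(result.genes) == [r[0] for r in oracle]

    def test_fewer_than_k_returns_all_survivors(self):
        degs = deg_frame([(f"g{i}", "C0", 1.0 + i, 0.01) for i in range(5)])
        assert len(top_upregulated(degs, "C0", k=20).genes) == 5

    def test_tie_broken_by_lexicographic_symbol(self):
        degs = deg_frame([("zeta", "C0", 2.0, 0.01), ("alpha", "C0", 2.0, 0.01),
                          ("mid", "C0", 3.0, 0.01)])
        result = top_upregulated(degs, "C0", k=2)
        assert list(result.genes) == ["mid", "alpha"]

    def test_missing_cluster_raises(self):
        degs = deg_frame([("g1", "C0", 1.0, 0.01)])
        with pytest.raises(KeyError, match="C7"):
            top_upregulated(degs, "C7")


class TestJaccard:
    def test_identical_sets_give_one(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_ten_of_twenty_shared_gives_one_third(self):
        a = {f"s{i}" for i in range(10)} | {f"a{i}" for i in range(10)}
        b = {f"s{i}" for i in range(10)} | {f"b{i}" for i in range(10)}
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_empty_sets_warn_and_give_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert jaccard(set(), set()) == 0.0

    @given(gene_sets_st, gene_sets_st)
    def test_bounds_symmetry_and_self_similarity(self, a, b):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty-vs-empty case
            j = jaccard(a, b)
            assert 0.0 <= j <= 1.0
            assert j == jaccard(b, a)
        if a:
            assert jaccard(a, a) == 1.0


class TestJaccardMatrix:
    def test_requires_two_clusters(self):
        with pytest.raises(ValueError, match="at least 2"):
            jaccard_matrix([ClusterGeneSet("C0", ("a",))])

    def test_identical_sets_give_all_ones(self):
        sets = [ClusterGeneSet("C0", ("a", "b")), ClusterGeneSet("C1", ("a", "b"))]
        m = jaccard_matrix(sets)
        assert np.array_equal(m.values, np.ones((2, 2)))

    def test_symmetric_with_unit_diagonal(self, rng):
        sets = [
            ClusterGeneSet(f"C{i}", tuple(
                rng.choice([f"g{j}" for j in range(40)], 15, replace=False)))
            for i in range(6)
        ]
        m = jaccard_matrix(sets)
        assert np.array_equal(m.values, m.values.T)
        assert np.array_equal(np.diag(m.values), np.ones(6))


def _block_matrix(perm=None):
    """Planted blocks {C0,C3,C8} and {C1,C4} with outlier C9."""
    clusters = ["C0", "C3", "C8", "C1", "C4", "C9"]
    values = np.eye(6)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        values[i, j] = values[j, i] = 0.6
    values[3, 4] = values[4, 3] = 0.7
    if perm is not None:
        clusters = [clusters[p] for p in perm]
        values = values[np.ix_(perm, perm)]
    return JaccardMatrix(clusters, values)


class TestMergeSubtypes:
    def test_recovers_planted_blocks_and_excludes_outlier(self):
        assignment = merge_subtypes(_block_matrix(), n_subtypes=2)
        assert assignment.members("Subtype_1") == ["C0", "C3", "C8"]
        assert assignment.members("Subtype_2") == ["C1", "C4"]
        assert assignment.mapping["C9"] == "excluded"

    def test_invariant_to_cluster_order(self, rng):
        reference = merge_subtypes(_block_matrix(), n_subtypes=2).mapping
        for _ in range(5):
            perm = list(rng.permutation(6))
            shuffled = merge_subtypes(_block_matrix(perm), n_subtypes=2).mapping
            assert shuffled == reference

    def test_all_zero_similarity_is_an_error(self):
        m = JaccardMatrix(["C0", "C1"], np.eye(2))
        with pytest.raises(ValueError, match="no mergeable structure"):
            merge_subtypes(m, n_subtypes=1)

    def test_too_few_clusters_after_exclusion(self):
        values = np.eye(3)
        values[0, 1] = values[1, 0] = 0.5
        m = JaccardMatrix(["C0", "C1", "C9"], values)
        with pytest.raises(ValueError, match="cannot form 3"):
            merge_subtypes(m, n_subtypes=3)

    def test_agrees_with_bruteforce_complete_linkage(self, rng):
        """Agglomerative result matches a hand-rolled greedy merge sequence."""
        for _ in range(10):
            n = 6
            sim = rng.random((n, n)) * 0.9
            sim = (sim + sim.T) / 2 + 0.05  # strictly positive, symmetric
            np.fill_diagonal(sim, 1.0)
            m = JaccardMatrix([f"C{i}" for i in range(n)], sim)
            got = merge_subtypes(m, n_subtypes=2)

            # oracle: greedy complete-linkage on 1 - J until two groups remain
            dist = 1.0 - sim
            groups = [{i} for i in range(n)]
            while len(groups) > 2:
                best = None
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        d = max(dist[i, j] for i in groups[a] for j in groups[b])
                        if best is None or d < best[0]:
                            best = (d, a, b)
                _, a, b = best
                groups[a] |= groups[b]
                del groups[b]
            groups.sort(key=lambda g: (-len(g), min(g)))
            expected = {}
            for rank, members in enumerate(groups, start=1):
                for i in members:
                    expected[f"C{i}"] = f"Subtype_{rank}"
            assert got.mapping == expected


class TestGeneratorRecovery:
    def test_planted_partition_recovered_from_deg_fixture(self):
        config = SyntheticConfig(seed=11)
        degs, truth = generate_deg_tables(config)
        sets = cluster_gene_sets(degs, k=config.k_top)
        matrix = jaccard_matrix(sets)
        assignment = merge_subtypes(matrix, n_subtypes=2)
        assert assignment.mapping == truth

    def test_block_structure_matches_analytic_values(self):
        config = SyntheticConfig(seed=3)
        degs, _ = generate_deg_tables(config)
        sets = {s.cluster: s.gene_set for s in cluster_gene_sets(degs)}
        b1, b2 = config.subtype_blocks
        assert jaccard(sets[b1[0]], sets[b1[1]]) == pytest.approx(1 / 3)
        assert jaccard(sets[b1[0]], sets[b2[0]]) == 0.0
        assert all(jaccard(sets["C9"], sets[c]) == 0.0
                   for c in config.clusters if c != "C9")
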