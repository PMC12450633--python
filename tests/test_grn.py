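import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from hepacre.cre import CRECall, assign_genes, call_enhancers, call_promoters
from hepacre.grn import (
    EnhancerLink,
    benjamini_hochberg,
    build_enhancer_network,
    build_promoter_network,
    motif_enrichment,
    read_link_table,
    write_link_table,
)
from hepacre.intervals import GenomicInterval
from hepacre.synthetic import (
    SyntheticConfig,
    generate_condition_deg_table,
    generate_gene_annotation,
    generate_link_tables,
    generate_motif_occurrences,
    generate_peaks_and_histone,
)
from hepacre.markers import upregulated_in_condition


def occ_frame(pairs):
    return pd.DataFrame(pairs, columns=["peak_id", "motif"])


class TestMotifEnrichment:
    def test_exact_hypergeometric_tail(self):
        # N=10 background, K=4 with motif, n=5 target, k=4 ->
        # p = C(4,4)*C(6,1)/C(10,5) = 6/252
        background = {f"p{i}" for i in range(10)}
        target = {f"p{i}" for i in range(5)}
        occ = occ_frame([(f"p{i}", "M1") for i in range(4)])
        result = motif_enrichment(target, background, occ)
        assert result.loc[0, "p_value"] == pytest.approx(6 / 252, abs=1e-12)

    def test_ubiquitous_motif_has_p_one(self):
        background = {f"p{i}" for i in range(8)}
        occ = occ_frame([(p, "M1") for p in background])
        result = motif_enrichment(set(list(background)[:3]), background, occ)
        assert result.loc[0, "p_value"] == pytest.approx(1.0)

    def test_target_equal_background_gives_unit_fold(self):
        background = {f"p{i}" for i in range(6)}
        occ = occ_frame([(f"p{i}", "M1") for i in range(3)]
                        + [(f"p{i}", "M2") for i in range(2, 6)])
        result = motif_enrichment(background, background, occ)
        assert (result["fold"] == 1.0).all()
        assert (result["k_target"] == result["K_background"]).all()

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            motif_enrichment({"a"}, {"b"}, occ_frame([]))

    def test_bh_adjustment_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(benjamini_hochberg(p), expected)

    def test_q_values_monotone_in_p_rank(self, rng):
        background = {f"p{i}" for i in range(50)}
        target = {f"p{i}" for i in range(12)}
        pairs = [(f"p{i}", f"M{j}") for j in range(15) for i in range(50)
                 if rng.random() < 0.2]
        result = motif_enrichment(target, background, occ_frame(pairs))
        ordered = result.sort_values("p_value")
        assert (ordered["q_value"].diff().dropna() >= -1e-12).all()


class TestPromoterNetwork:
    def fixture(self, seed=13):
        config = SyntheticConfig(seed=seed, n_atac_peaks=200, n_genes=400)
        bundle = generate_peaks_and_histone(config, "HTN")
        annotation = generate_gene_annotation(config)
        promoters = assign_genes(
            call_promoters(bundle.peaks, bundle.tracks["H3K4me3"]), annotation)
        occ, true_edges = generate_motif_occurrences(config)
        degs = generate_condition_deg_table(config)
        up = set(upregulated_in_condition(degs, config.condition_contrast))
        return config, promoters, occ, up, true_edges

    def test_recovers_planted_edges_exactly(self):
        config, promoters, occ, up, true_edges = self.fixture()
        edges = build_promoter_network(up, promoters, occ,
                                       set(config.tf_names))
        assert sorted((e.tf, e.cre_id, e.gene) for e in edges) == true_edges

    def test_cyp3a4_promoter_carries_five_tf_edges(self):
        config, promoters, occ, up, _ = self.fixture()
        edges = build_promoter_network(up, promoters, occ,
                                       set(config.tf_names))
        assert sum(1 for e in edges if e.gene == "CYP3A4") == 5

    def test_gene_without_promoter_call_gets_no_edges(self):
        config, promoters, occ, up, _ = self.fixture()
        others = [c for c in promoters if c.gene != "CYP3A4"]
        edges = build_promoter_network(up, others, occ, set(config.tf_names))
        assert not any(e.gene == "CYP3A4" for e in edges)

    def test_edge_count_bounded_by_occurrences(self):
        config, promoters, occ, up, _ = self.fixture()
        edges = build_promoter_network(up, promoters, occ, set(config.tf_names))
        promoter_ids = {c.cre_id for c in promoters}
        assert len(edges) <= (occ["peak_id"].isin(promoter_ids)).sum()

    def test_self_loop_flagged_not_dropped(self):
        iv = GenomicInterval("chr1", 0, 100, "pk", peak_category="Promoter")
        call = CRECall(iv, "promoter", frozenset({"H3K4me3"}), gene="GATA4")
        occ = occ_frame([("pk", "GATA4")])
        edges = build_promoter_network({"GATA4"}, [call], occ, {"GATA4"})
        assert len(edges) == 1 and edges[0].is_self_loop


def link(chrom, start, end, gene, tf=None, source="inferred"):
    return EnhancerLink(GenomicInterval(chrom, start, end, "l"), gene,
                        tf=tf, source=source)


def enhancer_call(chrom, start, end, name):
    iv = GenomicInterval(chrom, start, end, name, peak_category="Distal")
    return CRECall(iv, "enhancer", frozenset({"H3K4me1", "H3K27ac"}))


class TestEnhancerNetwork:
    def test_curated_support_without_histone_removed(self):
        inferred = [link("chr1", 0, 500, "G1", tf="TF1")]
        curated = [link("chr1", 100, 600, "G1", source="curated")]
        result = build_enhancer_network(inferred, curated, [])
        assert result.edges == []
        assert result.venn_pairs["inferred&curated"] == 1

    def test_gene_mismatch_breaks_curated_support(self):
        inferred = [link("chr1", 0, 500, "G1", tf="TF1")]
        curated = [link("chr1", 100, 600, "G2", source="curated")]
        calls = [enhancer_call("chr1", 0, 500, "e1")]
        assert build_enhancer_network(inferred, curated, calls).edges == []
        relaxed = build_enhancer_network(inferred, curated, calls,
                                         require_gene_match=False)
        assert len(relaxed.edges) == 1

    def test_identical_evidence_sets_keep_every_link(self):
        inferred = [link("chr1", i * 1000, i * 1000 + 500, f"G{i}", tf="TF1")
                    for i in range(5)]
        curated = [link("chr1", i * 1000, i * 1000 + 500, f"G{i}",
                        source="curated") for i in range(5)]
        calls = [enhancer_call("chr1", i * 1000, i * 1000 + 500, f"e{i}")
                 for i in range(5)]
        result = build_enhancer_network(inferred, curated, calls)
        assert len(result.edges) == 5
        assert result.venn_pairs["inferred&curated&histone"] == 5

    def test_generator_fixture_survivors_match_truth(self, small_config):
        inferred, curated, truth = generate_link_tables(small_config)
        bundle = generate_peaks_and_histone(small_config, "HTN")
        calls = call_enhancers(bundle.peaks, bundle.tracks["H3K4me1"],
                               bundle.tracks["H3K27ac"])
        result = build_enhancer_network(inferred, curated, calls)
        assert sorted((e.tf, e.cre_id, e.gene) for e in result.edges) == truth
        assert len(result.edges) == small_config.n_triple_supported


def test_link_table_round_trip(tmp_path):
    links = [link("chr1", 0, 500, "G1", tf="TF1"),
             link("chr2", 100, 700, "G2", source="curated")]
    path = tmp_path / "links.tsv"
    write_link_table(links, path)
    recovered = read_link_table(path)
    assert [(l.enhancer.chrom, l.enhancer.start, l.enhancer.end, l.gene, l.tf,
             l.source) for l in recovered] == \
           [("chr1", 0, 500, "G1", "TF1", "inferred"),
            ("chr2", 100, 700, "G2", None, "curated")]
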