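import numpy as np
import pandas as pd
import pytest

from fflpipe import PipelineConfig
from fflpipe.ffl_mining import (
    build_ffl_network,
    conservation_filter,
    enumerate_ffls,
    filter_edges,
    fit_power_law,
    normalize_mirna,
    topology_stats,
)
from _oracles import brute_ffl_scan


def edge_frame(rows):
    return pd.DataFrame(rows, columns=["source", "target", "edge_type"])


def raw_edge(source, target, edge_type, dialect="mirwalk", species="human",
             **overrides):
    row = {"source": source, "target": target, "edge_type": edge_type,
           "species": species, "dialect": dialect,
           "score": np.nan, "region": np.nan, "binding_gap": np.nan,
           "confidence_flag": np.nan, "upstream_bp": np.nan,
           "evidence_p": np.nan}
    if dialect == "mirwalk":
        row.update(score=0.99, region="3UTR", binding_gap=1)
    elif dialect == "starbase":
        row.update(score=0.99)
    elif dialect == "mirsearch":
        row.update(confidence_flag="high")
    elif dialect == "chipbase":
        row.update(upstream_bp=500)
    elif dialect == "enrichr_tf":
        row.update(evidence_p=0.01)
    row.update(overrides)
    return row


class TestNormalizeMirna:
    @pytest.mark.parametrize("name,expected", [
        ("hsa-miR-34b-5p", "mir-34b-5p"),
        ("mmu-miR-34b-5p", "mir-34b-5p"),
        ("MMU-MIR-449c", "mir-449c"),
    ])
    def test_species_prefix_stripped_case_folded(self, name, expected):
        assert normalize_mirna(name) == expected

    def test_arm_suffix_kept_by_default_dropped_on_request(self):
        assert normalize_mirna("hsa-miR-449c-5p") == "mir-449c-5p"
        assert normalize_mirna("hsa-miR-449c-5p", keep_arm=False) == "mir-449c"


class TestFilterEdges:
    def test_mirna_score_threshold_inclusive(self, config):
        raw = pd.DataFrame([
            raw_edge("m1", "g1", "mirna_gene", score=0.94),
            raw_edge("m2", "g1", "mirna_gene", score=0.95),
        ])
        kept = filter_edges(raw, config)
        assert list(kept["source"]) == ["m2"]

    def test_mirwalk_needs_3utr_and_unit_binding_gap(self, config):
        raw = pd.DataFrame([
            raw_edge("m1", "g1", "mirna_gene", region="CDS"),
            raw_edge("m2", "g1", "mirna_gene", binding_gap=2),
            raw_edge("m3", "g1", "mirna_gene"),
        ])
        assert list(filter_edges(raw, config)["source"]) == ["m3"]

    def test_upstream_window_boundary(self, config):
        raw = pd.DataFrame([
            raw_edge("t1", "g1", "tf_gene", dialect="chipbase", upstream_bp=1000),
            raw_edge("t2", "g1", "tf_gene", dialect="chipbase", upstream_bp=1001),
        ])
        assert list(filter_edges(raw, config)["source"]) == ["t1"]

    def test_tf_evidence_p_strict(self, config):
        raw = pd.DataFrame([
            raw_edge("t1", "g1", "tf_gene", dialect="enrichr_tf", evidence_p=0.05),
            raw_edge("t2", "g1", "tf_gene", dialect="enrichr_tf", evidence_p=0.049),
        ])
        assert list(filter_edges(raw, config)["source"]) == ["t2"]

    def test_itfp_edges_kept_unfiltered(self, config):
        raw = pd.DataFrame([raw_edge("t1", "g1", "tf_gene", dialect="itfp")])
        assert len(filter_edges(raw, config)) == 1

    def test_same_pair_from_two_dialects_merged(self, config):
        raw = pd.DataFrame([
            raw_edge("m1", "g1", "mirna_gene", dialect="mirwalk"),
            raw_edge("m1", "g1", "mirna_gene", dialect="starbase"),
        ])
        kept = filter_edges(raw, config)
        assert len(kept) == 1
        assert kept.loc[0, "provenance"] == "mirwalk;starbase"

    def test_missing_dialect_column_located(self, config):
        raw = pd.DataFrame([raw_edge("m1", "g1", "mirna_gene", score=np.nan)])
        with pytest.raises(ValueError, match="row 0.*'score'"):
            filter_edges(raw, config)

    def test_self_edge_rejected(self, config):
        raw = pd.DataFrame([raw_edge("x", "x", "mirna_gene")])
        with pytest.raises(ValueError, match="self-edge"):
            filter_edges(raw, config)


class TestConservationFilter:
    def _human(self):
        return edge_frame([
            ("hsa-miR-34b-5p", "TF1", "mirna_tf"),
            ("hsa-miR-34b-5p", "G1", "mirna_gene"),
            ("hsa-miR-999-5p", "G1", "mirna_gene"),
            ("TF1", "G1", "tf_gene"),
        ])

    def test_shared_base_name_retained(self):
        mouse = edge_frame([("mmu-miR-34b-5p", "G1", "mirna_gene")])
        final, pruned = conservation_filter(self._human(), mouse)
        assert final == {"hsa-miR-34b-5p"}
        assert "hsa-miR-999-5p" not in set(pruned["source"])

    def test_tf_gene_edges_untouched(self):
        mouse = edge_frame([])
        _, pruned = conservation_filter(self._human(), mouse)
        assert ("TF1", "G1") in set(map(tuple, pruned[["source", "target"]]
                                        .to_numpy()))

    def test_empty_mouse_removes_all_mirna_edges(self):
        final, pruned = conservation_filter(self._human(), edge_frame([]))
        assert final == set()
        assert set(pruned["edge_type"]) == {"tf_gene"}

    def test_idempotent(self):
        mouse = edge_frame([("mmu-miR-34b-5p", "G1", "mirna_gene")])
        final1, pruned1 = conservation_filter(self._human(), mouse)
        final2, pruned2 = conservation_filter(pruned1, mouse)
        assert final1 == final2
        assert pruned1.equals(pruned2)


class TestEnumerateFfls:
    def test_complete_triple_found(self):
        edges = edge_frame([("m1", "T1", "mirna_tf"),
                            ("m1", "g1", "mirna_gene"),
                            ("T1", "g1", "tf_gene")])
        out = enumerate_ffls(edges)
        assert out.to_dict("records") == [
            {"mirna": "m1", "tf": "T1", "gene": "g1"}]

    @pytest.mark.parametrize("drop", [0, 1, 2])
    def test_removing_any_edge_destroys_the_loop(self, drop):
        rows = [("m1", "T1", "mirna_tf"), ("m1", "g1", "mirna_gene"),
                ("T1", "g1", "tf_gene")]
        del rows[drop]
        assert enumerate_ffls(edge_frame(rows)).empty

    def test_invariant_to_order_and_duplicates(self):
        rows = [("m1", "T1", "mirna_tf"), ("m1", "g1", "mirna_gene"),
                ("T1", "g1", "tf_gene")]
        shuffled = edge_frame(rows[::-1] + rows)
        assert enumerate_ffls(shuffled).equals(enumerate_ffls(edge_frame(rows)))

    def test_matches_brute_force_on_random_tripartite_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n_m, n_t, n_g = rng.integers(1, 16, size=3)
            rows = []
            for m in range(n_m):
                for t in range(n_t):
                    if rng.random() < 0.15:
                        rows.append((f"m{m}", f"T{t}", "mirna_tf"))
            for m in range(n_m):
                for g in range(n_g):
                    if rng.random() < 0.15:
                        rows.append((f"m{m}", f"g{g}", "mirna_gene"))
            for t in range(n_t):
                for g in range(n_g):
                    if rng.random() < 0.15:
                        rows.append((f"T{t}", f"g{g}", "tf_gene"))
            got = {tuple(r) for r in
                   enumerate_ffls(edge_frame(rows)).to_numpy()}
            assert got == brute_ffl_scan(rows)


class TestBuildFflNetwork:
    def test_single_loop_counts(self):
        motifs = pd.DataFrame([{"mirna": "m1", "tf": "T1", "gene": "g1"}])
        net = build_ffl_network(motifs)
        assert net.n_nodes == 3 and net.n_edges == 3
        assert net.edge_type_counts() == {
            "mirna_gene": 1, "mirna_tf": 1, "tf_gene": 1}

    def test_two_loops_sharing_tf_and_gene(self):
        motifs = pd.DataFrame([
            {"mirna": "m1", "tf": "T1", "gene": "g1"},
            {"mirna": "m2", "tf": "T1", "gene": "g1"},
        ])
        net = build_ffl_network(motifs)
        assert net.n_nodes == 4
        assert net.n_edges == 5

    def test_count_identities(self):
        motifs = pd.DataFrame([
            {"mirna": "m1", "tf": "T1", "gene": "g1"},
            {"mirna": "m1", "tf": "T2", "gene": "g2"},
            {"mirna": "m2", "tf": "T1", "gene": "g1"},
        ])
        net = build_ffl_network(motifs)
        assert sum(net.edge_type_counts().values()) == net.n_edges
        assert len(net.mirnas) + len(net.tfs) + len(net.genes) == net.n_nodes
        summary = net.summary_table()
        assert summary["n_edges"].sum() == net.n_edges


class TestTopologyStats:
    def test_triangle_clustering_and_distances(self):
        motifs = pd.DataFrame([{"mirna": "m", "tf": "T", "gene": "g"}])
        stats = topology_stats(build_ffl_network(motifs))
        assert (stats["node_table"]["clustering"] == 1.0).all()
        assert stats["path_length_histogram"] == {1: 3}

    def test_four_cycle_path_histogram(self):
        import networkx as nx
        from fflpipe.ffl_mining import FFLNetwork
        edges = pd.DataFrame([
            ("a", "b", "mirna_tf"), ("b", "c", "tf_gene"),
            ("c", "d", "mirna_gene"), ("d", "a", "mirna_tf")],
            columns=["source", "target", "edge_type"])
        net = FFLNetwork(motifs=pd.DataFrame(), mirnas=("a", "c"),
                         tfs=("b", "d"), genes=(), edges=edges)
        stats = topology_stats(net)
        assert (stats["node_table"]["clustering"] == 0.0).all()
        assert stats["path_length_histogram"] == {1: 4, 2: 2}

    def test_star_power_law_closed_form(self):
        from fflpipe.ffl_mining import FFLNetwork
        n_leaves = 8
        edges = pd.DataFrame(
            [("hub", f"leaf{i}", "mirna_tf") for i in range(n_leaves)],
            columns=["source", "target", "edge_type"])
        net = FFLNetwork(motifs=pd.DataFrame(), mirnas=("hub",),
                         tfs=tuple(f"leaf{i}" for i in range(n_leaves)),
                         genes=(), edges=edges)
        stats = topology_stats(net)
        assert stats["degree_histogram"] == {1: n_leaves, n_leaves: 1}
        # two-point regression through (log 1, log n) and (log n, log 1)
        fit = stats["power_law_fit"]
        assert fit["slope"] == pytest.approx(-1.0)
        assert fit["intercept"] == pytest.approx(np.log10(n_leaves))
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_single_bin_fit_is_degenerate_but_defined(self):
        fit = fit_power_law({2: 5})
        assert fit["slope"] == 0.0 and fit["r_squared"] == 1.0

    def test_topological_coefficient_square(self):
        from fflpipe.ffl_mining import FFLNetwork
        edges = pd.DataFrame([
            ("a", "b", "mirna_tf"), ("b", "c", "tf_gene"),
            ("c", "d", "mirna_gene"), ("d", "a", "mirna_tf")],
            columns=["source", "target", "edge_type"])
        net = FFLNetwork(motifs=pd.DataFrame(), mirnas=("a", "c"),
                         tfs=("b", "d"), genes=(), edges=edges)
        stats = topology_stats(net)
        # in C4 every node's sole shared-neighbor partner is the opposite
        # corner with J = 2 shared neighbors, so T = 2/2 = 1... but each
        # node also shares neighbors with itself excluded; partners are
        # the single opposite node only
        assert (stats["node_table"]["topological_coefficient"] == 1.0).all()
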