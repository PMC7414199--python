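import numpy as np
import pandas as pd
import pytest

from fflpipe import (
    PipelineConfig,
    SyntheticSpec,
    build_ppi,
    enumerate_ffls,
    filter_edges,
    gen_expression,
    gen_ppi,
    gen_regulatory,
    gen_table1_regulatory,
)
from fflpipe.synthetic import _exact_tripartite, gen_probe_matrix


class TestSpecValidation:
    def test_planted_counts_bounded_by_gene_count(self):
        with pytest.raises(ValueError, match="exceeds n_genes"):
            SyntheticSpec(n_genes=10, n_de_up=6, n_de_down=6)

    def test_fractions_bounded(self):
        with pytest.raises(ValueError, match="conserved_frac"):
            SyntheticSpec(conserved_frac=1.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            gen_expression(SyntheticSpec(n_case=1))


class TestGenExpression:
    def test_noiseless_limit_recovers_planted_effect(self):
        spec = SyntheticSpec(n_genes=50, n_de_up=5, n_de_down=5,
                             effect_lfc=1.0, noise_sd=1e-12, seed=1)
        studies, truth = gen_expression(spec)
        up = truth.loc[truth["direction"] == "up", "gene"]
        for study in studies:
            diff = (study.case_matrix().mean(axis=1)
                    - study.control_matrix().mean(axis=1))
            np.testing.assert_allclose(diff[up], 1.0, atol=1e-9)

    def test_no_planted_genes_gives_empty_truth(self):
        spec = SyntheticSpec(n_genes=20, n_de_up=0, n_de_down=0, seed=2)
        _, truth = gen_expression(spec)
        assert truth.empty

    def test_shared_genes_disjoint_samples(self):
        spec = SyntheticSpec(n_genes=500, n_de_up=25, n_de_down=25,
                             effect_lfc=1.5, noise_sd=0.5,
                             n_case=10, n_control=10, seed=7)
        studies, _ = gen_expression(spec)
        assert len(studies) == 2
        assert studies[0].genes.equals(studies[1].genes)
        assert not (set(studies[0].samples) & set(studies[1].samples))

    def test_reproducible_byte_for_byte(self):
        spec = SyntheticSpec(n_genes=30, seed=9, n_de_up=3, n_de_down=3)
        a, _ = gen_expression(spec)
        b, _ = gen_expression(spec)
        for s1, s2 in zip(a, b):
            assert s1.data.equals(s2.data)

    def test_probe_expansion_collapses_back_exactly(self):
        from fflpipe.meta_deg import collapse_probes
        spec = SyntheticSpec(n_genes=30, seed=4, n_de_up=3, n_de_down=3)
        studies, _ = gen_expression(spec)
        matrix, mapping = gen_probe_matrix(studies[0], n_multi_probe=5)
        from fflpipe.meta_deg import ExpressionStudy
        probe_study = ExpressionStudy("s", matrix, studies[0].groups)
        back = collapse_probes(probe_study, mapping)
        pd.testing.assert_frame_equal(
            back.data.sort_index(), studies[0].data.sort_index(),
            check_names=False)


class TestGenPpi:
    def test_every_seed_connected(self):
        spec = SyntheticSpec(seed=3)
        seeds = [f"S{i}" for i in range(8)]
        biogrid, hippie = gen_ppi(seeds, spec, spec.rng())
        touched = set(biogrid["partner_a"]) | set(biogrid["partner_b"]) \
            | set(hippie["partner_a"]) | set(hippie["partner_b"])
        assert set(seeds) <= touched

    def test_subthreshold_edges_equal_those_removed_by_build(self, config):
        spec = SyntheticSpec(seed=7)
        seeds = [f"S{i}" for i in range(8)]
        biogrid, hippie = gen_ppi(seeds, spec, spec.rng())
        n_bad = int((hippie["score"] < config.hippie_min_score).sum()
                    + (biogrid["evidence_count"] < 1).sum())
        graph = build_ppi(seeds, biogrid, hippie, config)
        n_kept = graph.number_of_edges()
        assert n_kept == len(biogrid) + len(hippie) - n_bad

    def test_zero_extra_partners_gives_only_seed_seed_edges(self, config):
        spec = SyntheticSpec(seed=5, ppi_extra_partners=0.0)
        biogrid, hippie = gen_ppi(["A", "B"], spec, spec.rng(),
                                  n_designated_hubs=0, n_below_threshold=0)
        graph = build_ppi(["A", "B"], biogrid, hippie, config)
        assert set(graph.nodes) == {"A", "B"}

    def test_zero_extra_partners_single_seed_is_isolated(self, config):
        spec = SyntheticSpec(seed=5, ppi_extra_partners=0.0)
        biogrid, hippie = gen_ppi(["A"], spec, spec.rng(),
                                  n_designated_hubs=0, n_below_threshold=0)
        graph = build_ppi(["A"], biogrid, hippie, config)
        assert set(graph.nodes) == {"A"}
        assert graph.number_of_edges() == 0


class TestGenRegulatory:
    def test_single_planted_loop_no_decoys(self):
        spec = SyntheticSpec(n_planted_ffl=1, decoy_edge_frac=0.0, seed=3)
        human, _, truth = gen_regulatory(spec)
        assert len(human) == 3
        config = PipelineConfig()
        kept = filter_edges(human, config)
        found = enumerate_ffls(kept)
        assert len(found) == 1
        assert found.loc[0].tolist() == truth.loc[0].tolist()

    def test_zero_conservation_leaves_no_final_mirnas(self):
        from fflpipe import conservation_filter
        spec = SyntheticSpec(n_planted_ffl=3, conserved_frac=0.0, seed=4)
        human, mouse, _ = gen_regulatory(spec)
        config = PipelineConfig()
        final, pruned = conservation_filter(
            filter_edges(human, config), filter_edges(mouse, config))
        assert final == set()
        assert enumerate_ffls(pruned).empty

    def test_decoys_never_complete_unplanted_loops(self):
        spec = SyntheticSpec(n_planted_ffl=8, decoy_edge_frac=0.5, seed=11,
                             conserved_frac=1.0)
        human, mouse, truth = gen_regulatory(spec)
        config = PipelineConfig()
        from fflpipe import conservation_filter
        final, pruned = conservation_filter(
            filter_edges(human, config), filter_edges(mouse, config))
        found = {tuple(r) for r in enumerate_ffls(pruned).to_numpy()}
        planted = {tuple(r) for r in truth.to_numpy()}
        assert found <= planted

    def test_failing_score_rows_are_filtered(self):
        spec = SyntheticSpec(n_planted_ffl=4, decoy_edge_frac=0.5, seed=6)
        human, _, _ = gen_regulatory(spec)
        config = PipelineConfig()
        kept = filter_edges(human, config)
        assert len(kept) < len(human)

    def test_reproducible(self):
        spec = SyntheticSpec(n_planted_ffl=5, seed=13)
        h1, m1, t1 = gen_regulatory(spec)
        h2, m2, t2 = gen_regulatory(spec)
        assert h1.equals(h2) and m1.equals(m2) and t1.equals(t2)


class TestExactTripartite:
    def test_published_count_mode(self):
        edges = _exact_tripartite(26, 20, 5, 32, 21, 144)
        assert len(edges["mirna_gene"]) == 32
        assert len(edges["tf_gene"]) == 21
        assert len(edges["mirna_tf"]) == 144

    def test_every_node_and_edge_in_a_loop(self):
        edges = _exact_tripartite(6, 5, 3, 10, 6, 12)
        rows = []
        for et, pairs in edges.items():
            for a, b in pairs:
                rows.append((f"{et[0]}{a}" if et != "tf_gene" else f"t{a}",
                             b, et))
        # verify via the motif scan on string labels
        typed = []
        for m, g in edges["mirna_gene"]:
            typed.append((f"M{m}", f"G{g}", "mirna_gene"))
        for t, g in edges["tf_gene"]:
            typed.append((f"T{t}", f"G{g}", "tf_gene"))
        for m, t in edges["mirna_tf"]:
            typed.append((f"M{m}", f"T{t}", "mirna_tf"))
        frame = pd.DataFrame(typed, columns=["source", "target", "edge_type"])
        motifs = enumerate_ffls(frame)
        from fflpipe import build_ffl_network
        net = build_ffl_network(motifs)
        assert net.n_edges == len(frame)
        assert net.n_nodes == 6 + 5 + 3

    def test_infeasible_requests_explained(self):
        with pytest.raises(ValueError, match="e_mg"):
            _exact_tripartite(5, 5, 3, 4, 5, 10)
        with pytest.raises(ValueError, match="e_mt"):
            _exact_tripartite(3, 3, 2, 5, 4, 100)
        with pytest.raises(ValueError, match="n_tf >= n_gene"):
            _exact_tripartite(3, 2, 4, 8, 5, 5)

    def test_table1_generator_round_trip(self):
        human, mouse, truth = gen_table1_regulatory(seed=2)
        config = PipelineConfig()
        from fflpipe import conservation_filter
        final, pruned = conservation_filter(
            filter_edges(human, config), filter_edges(mouse, config))
        assert len(final) == 26
        motifs = enumerate_ffls(pruned)
        assert motifs.equals(truth)
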