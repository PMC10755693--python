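"""SSN construction, centrality, threshold selection, annotated export."""

import numpy as np
import pandas as pd
import pytest

from sqgsuite import ssn as sn
from sqgsuite.pairalign import ScoredPair
from oracles import brute_betweenness


def edge(a: str, b: str, AS: float) -> ScoredPair:
    """Fabricate a minimal ScoredPair carrying only what the SSN needs."""
    return ScoredPair(
        id_a=a, id_b=b, raw_score=0.0, bit_score=0.0,
        evalue_like=10.0 ** (-AS), alignment_score_AS=AS,
        percent_identity=0.0, aligned_length=0,
    )


class TestBuildGraph:
    def test_threshold_zero_keeps_connected_set_together(self):
        edges = [edge("a", "b", 5), edge("b", "c", 8), edge("c", "d", 3)]
        g = sn.build_graph(edges, 0.0)
        assert len(g.clusters()) == 1

    def test_threshold_above_max_as_gives_all_singletons(self):
        edges = [edge("a", "b", 5), edge("b", "c", 8)]
        g = sn.build_graph(edges, 100.0)
        assert len(g.clusters()) == 3
        assert all(len(c) == 1 for c in g.clusters())

    def test_two_family_fixture_splits_into_generating_families(
        self, two_families, two_family_edges
    ):
        famA, famB = two_families
        inter_max = max(e.alignment_score_AS for e in two_family_edges
                        if e.id_a[0] != e.id_b[0])
        intra_min = min(e.alignment_score_AS for e in two_family_edges
                        if e.id_a[0] == e.id_b[0])
        assert inter_max < intra_min  # the fixture really separates
        low = sn.build_graph(two_family_edges, 0.0)
        assert len(low.clusters()) == 1
        mid = sn.build_graph(two_family_edges, (inter_max + intra_min) / 2)
        assert len(mid.clusters()) == 2
        memberships = {frozenset(c) for c in mid.clusters()}
        assert memberships == {
            frozenset(r.id for r in famA), frozenset(r.id for r in famB),
        }

    def test_components_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        edges = [edge(f"n{a}", f"n{b}", float(rng.uniform(0, 50)))
                 for a, b in rng.integers(0, 15, size=(60, 2)) if a != b]
        counts = [len(sn.build_graph(edges, t).clusters())
                  for t in np.linspace(0, 60, 20)]
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_clusters_invariant_to_edge_order(self, two_family_edges):
        g1 = sn.build_graph(two_family_edges, 50.0)
        shuffled = list(two_family_edges)
        np.random.default_rng(0).shuffle(shuffled)
        g2 = sn.build_graph(shuffled, 50.0)
        assert g1.clusters() == g2.clusters()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            sn.build_graph([edge("a", "b", 1)], -1.0)


class TestCentrality:
    def test_path_graph_betweenness_closed_form(self):
        g = sn.build_graph([edge("a", "b", 10), edge("b", "c", 10)], 0.0)
        prof = sn.centrality_profile(g)
        assert prof.loc["b", "betweenness"] == 1.0  # unnormalised pair count
        assert prof.loc["a", "betweenness"] == 0.0
        assert prof.loc["c", "betweenness"] == 0.0

    def test_complete_graph_betweenness_zero(self):
        nodes = "abcd"
        edges = [edge(x, y, 10) for i, x in enumerate(nodes)
                 for y in nodes[i + 1:]]
        prof = sn.centrality_profile(sn.build_graph(edges, 0.0))
        assert (prof["betweenness"] == 0.0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_betweenness_matches_bruteforce_enumeration(self, seed):
        """Betweenness on random ≤12-node graphs equals all-shortest-paths
        enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        pairs = {(f"n{a}", f"n{b}") for a, b in rng.integers(0, n, (2 * n, 2))
                 if a < b}
        g = sn.build_graph([edge(a, b, 10) for a, b in pairs], 0.0)
        prof = sn.centrality_profile(g)
        oracle = brute_betweenness(list(g.graph.nodes), list(g.graph.edges))
        for node, expected in oracle.items():
            assert prof.loc[node, "betweenness"] == pytest.approx(
                expected, abs=1e-9
            )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            sn.centrality_profile(sn.SSNGraph(__import__("networkx").Graph(), 0))


class TestSelectThreshold:
    def test_two_family_fixture_selects_between_families(
        self, two_family_edges
    ):
        inter_max = max(e.alignment_score_AS for e in two_family_edges
                        if e.id_a[0] != e.id_b[0])
        intra_min = min(e.alignment_score_AS for e in two_family_edges
                        if e.id_a[0] == e.id_b[0])
        grid = list(np.linspace(0, intra_min - 1, 15))
        sweep = sn.select_threshold(grid, two_family_edges)
        assert sweep.status == "ok"
        assert inter_max < sweep.selected < intra_min

    def test_single_clique_selects_grid_minimum(self):
        nodes = "abcde"
        edges = [edge(x, y, 50) for i, x in enumerate(nodes)
                 for y in nodes[i + 1:]]
        sweep = sn.select_threshold([0, 10, 20, 30], edges)
        assert sweep.selected == 0.0

    def test_edgeless_grid_selects_nothing(self):
        edges = [edge("a", "b", 1)]  # below every grid point
        sweep = sn.select_threshold([5, 10, 15, 20], edges)
        assert sweep.selected is None
        assert sweep.status == "no plateau found"

    def test_sweep_table_is_complete(self, two_family_edges):
        grid = [0.0, 20.0, 40.0, 60.0]
        sweep = sn.select_threshold(grid, two_family_edges, strategy="manual")
        assert list(sweep.table["threshold"]) == grid
        assert {"n_clusters", "n_singletons", "mean_degree",
                "mean_betweenness"} <= set(sweep.table.columns)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            sn.select_threshold([1, 2], [edge("a", "b", 1)])


class TestExport:
    def _annotated(self, two_families, two_family_edges, tmp_path):
        famA, famB = two_families
        g = sn.build_graph(two_family_edges, 50.0)
        metadata = pd.DataFrame({
            "taxonomy": {r.id: r.taxonomy for r in famA + famB}
        })
        return sn.annotate_and_export(
            g, metadata, "taxonomy",
            xgmml_path=tmp_path / "net.xgmml",
            graphml_path=tmp_path / "net.graphml",
        )

    def test_two_taxa_get_two_color_classes(
        self, two_families, two_family_edges, tmp_path
    ):
        g = self._annotated(two_families, two_family_edges, tmp_path)
        colors = {g.graph.nodes[n]["color"] for n in g.graph.nodes}
        assert len(colors) == 2

    def test_xgmml_round_trip_is_lossless(
        self, two_families, two_family_edges, tmp_path
    ):
        g = self._annotated(two_families, two_family_edges, tmp_path)
        back = sn.read_xgmml(tmp_path / "net.xgmml")
        assert set(back.nodes) == set(g.graph.nodes)
        assert ({frozenset(e) for e in back.edges}
                == {frozenset(e) for e in g.graph.edges})
        for n in g.graph.nodes:
            assert back.nodes[n] == g.graph.nodes[n]
        for a, b in g.graph.edges:
            assert back.edges[a, b] == pytest.approx(g.graph.edges[a, b])

    def test_graphml_read_back(
        self, two_families, two_family_edges, tmp_path
    ):
        g = self._annotated(two_families, two_family_edges, tmp_path)
        back = sn.read_graphml(tmp_path / "net.graphml")
        assert set(back.nodes) == set(g.graph.nodes)

    def test_unannotated_nodes_are_labelled(self, two_family_edges):
        g = sn.build_graph(two_family_edges, 50.0)
        metadata = pd.DataFrame({"taxonomy": {"A_000": "t1"}})
        g = sn.annotate(g, metadata, "taxonomy")
        assert g.graph.nodes["B_000"]["label"] == "unannotated"

    def test_metadata_collision_rejected(self, two_family_edges):
        g = sn.build_graph(two_family_edges, 50.0)
        metadata = pd.DataFrame(
            {"taxonomy": ["t1", "t2"]}, index=["A_000", "A_000"]
        )
        with pytest.raises(ValueError, match="collision"):
            sn.annotate(g, metadata, "taxonomy")

    def test_pathway_context_scheme_uses_classifier_output(self):
        """Node labels under the pathway-context scheme equal the genome
        classifier's calls for the corresponding source genomes."""
        from sqgsuite.neighborhood import (
            classify_neighborhood, extract_neighborhood,
        )
        from sqgsuite.syndata import GenomeSpec, make_genome, seed_locus_of

        nodes, expected = [], {}
        for i, pathway in enumerate(["sulfo-EMP", "sulfo-SMO", "none"]):
            feats = make_genome(GenomeSpec(pathway_label=pathway, seed=40 + i))
            call = classify_neighborhood(
                extract_neighborhood(feats, seed_locus_of(feats))
            )
            node = f"protein_{i}"
            nodes.append(node)
            expected[node] = call.pathway
        g = sn.build_graph(
            [edge(nodes[0], nodes[1], 10), edge(nodes[1], nodes[2], 10)], 0.0
        )
        metadata = pd.DataFrame({"pathway_context": expected})
        g = sn.annotate(g, metadata, "pathway-context")
        for node in nodes:
            assert g.graph.nodes[node]["label"] == expected[node]
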