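"""Disease-network extraction, Girvan–Newman communities, enrichment."""

import networkx as nx
import numpy as np
import pytest

from frnrank.bayes import FunctionalNetwork
from frnrank.community import (
    extract_disease_network,
    girvan_newman_partition,
    hypergeometric_enrichment,
)
from frnrank.io import GeneSet, GeneSetCollection


def _network(genes, edges):
    post = np.zeros((len(genes), len(genes)))
    idx = {g: i for i, g in enumerate(genes)}
    for a, b, w in edges:
        post[idx[a], idx[b]] = post[idx[b], idx[a]] = w
    return FunctionalNetwork(list(genes), post)


class TestExtractDiseaseNetwork:
    def test_unreachable_threshold_leaves_isolated_top_genes(self):
        net = _network(list("ABC"), [("A", "B", 0.99)])
        g = extract_disease_network(net, ["A"], threshold=1.01)
        assert set(g.nodes) == {"A"} and g.number_of_edges() == 0

    def test_high_scoring_neighbor_included(self):
        net = _network(list("ABCDE"), [("A", "B", 0.99), ("A", "C", 0.5)])
        g = extract_disease_network(net, ["A"], threshold=0.98)
        assert set(g.nodes) == {"A", "B"}
        assert g.nodes["A"]["role"] == "top-decile"
        assert g.nodes["B"]["role"] == "neighbor"

    def test_neighbor_neighbor_edges_included(self):
        net = _network(
            list("ABC"),
            [("A", "B", 0.99), ("A", "C", 0.99), ("B", "C", 0.99)],
        )
        g = extract_disease_network(net, ["A"], threshold=0.98)
        assert g.has_edge("B", "C")


def _two_cliques_with_bridge():
    g = nx.Graph()
    for prefix in ("a", "b"):
        clique = [f"{prefix}{i}" for i in range(5)]
        for i, u in enumerate(clique):
            for v in clique[i + 1:]:
                g.add_edge(u, v)
    g.add_edge("a0", "b0")
    return g


class TestGirvanNewman:
    def test_two_cliques_split_at_bridge(self):
        part = girvan_newman_partition(_two_cliques_with_bridge())
        assert part.n_communities == 2
        comm_a = {n for n in part.community_of if n.startswith("a")}
        assert {part.community_of[n] for n in comm_a} == {part.community_of["a0"]}
        assert part.community_of["a0"] != part.community_of["b0"]

    def test_bridge_has_maximal_betweenness(self):
        g = _two_cliques_with_bridge()
        bet = nx.edge_betweenness_centrality(g, normalized=False)
        bridge = tuple(sorted(("a0", "b0")))
        assert max(bet, key=lambda e: bet[e]) in (bridge, bridge[::-1])
        assert bet[("a0", "b0")] == pytest.approx(25.0)

    def test_edgeless_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("ABCD")
        part = girvan_newman_partition(g)
        assert part.n_communities == 4
        assert part.modularity == 0.0

    def test_single_clique_one_community(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(6)})
        part = girvan_newman_partition(g)
        assert part.n_communities == 1

    def test_selected_partition_maximizes_modularity_over_sequence(self):
        # exhaustive check against every contiguous-removal partition
        g = _two_cliques_with_bridge()
        part = girvan_newman_partition(g)
        best = max(
            nx.community.modularity(g, p)
            for p in ({frozenset(g)}, set(map(frozenset, (
                {n for n in g if n.startswith("a")},
                {n for n in g if n.startswith("b")},
            ))))
        )
        assert part.modularity == pytest.approx(best)

    def test_invariant_to_node_insertion_order(self):
        g1 = _two_cliques_with_bridge()
        g2 = nx.Graph()
        for u, v in sorted(g1.edges, reverse=True):
            g2.add_edge(u, v)
        p1 = girvan_newman_partition(g1)
        p2 = girvan_newman_partition(g2)
        assert p1.community_of == p2.community_of
        assert p1.modularity == pytest.approx(p2.modularity)

    def test_community_ids_contiguous_from_one(self):
        part = girvan_newman_partition(_two_cliques_with_bridge())
        assert sorted(set(part.community_of.values())) == [1, 2]


def _sets(d):
    coll = GeneSetCollection()
    for name, genes in d.items():
        coll.sets[name] = GeneSet("", list(genes))
    return coll


class TestHypergeometricEnrichment:
    def test_closed_form_single_tail_term(self):
        universe = {f"g{i}" for i in range(20)}
        cluster = {f"g{i}" for i in range(10)}
        sets = _sets({"s": [f"g{i}" for i in range(5)]})
        df = hypergeometric_enrichment(cluster, sets, universe)
        assert df.loc[0, "p_value"] == pytest.approx(3003 / 184756, rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = {f"g{i}" for i in range(20)}
        df = hypergeometric_enrichment(
            {"g0", "g1"}, _sets({"s": ["g10", "g11"]}), universe
        )
        assert df.loc[0, "p_value"] == 1.0

    def test_bh_stepup_hand_example(self):
        universe = {f"g{i}" for i in range(40)}
        # four sets engineered to give increasing p-values
        cluster = {f"g{i}" for i in range(10)}
        sets = _sets({f"s{j}": [f"g{i}" for i in range(j, j + 12)] for j in range(4)})
        df = hypergeometric_enrichment(cluster, sets, universe)
        # recompute BH by the textbook step-up definition
        ps = df["p_value"].to_numpy()
        m = len(ps)
        expected = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(df["q_value"], np.minimum(expected, 1.0))
        assert (df["q_value"] >= df["p_value"] - 1e-15).all()

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), _sets({"s": ["a"]}), {"a"})

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"x"}, _sets({"s": ["a"]}), {"a"})


def test_bh_matches_textbook_stepup_on_random_vectors(rng):
    """BH correction equals the step-up definition on random p-vectors."""
    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        m = int(rng.integers(1, 12))
        ps = rng.random(m)
        _, q, _, _ = multipletests(ps, method="fdr_bh")
        order = np.argsort(ps, kind="mergesort")
        ranked = ps[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)
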