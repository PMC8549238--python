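import itertools

import networkx as nx
import numpy as np
import pytest

from dietnet import communities as comm

TRIANGLE = [("a", "b"), ("a", "c"), ("b", "c")]
TWO_TRIANGLES = TRIANGLE + [("x", "y"), ("x", "z"), ("y", "z")]
STAR = [("hub", f"leaf{i}") for i in range(1, 5)]
BOWTIE = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("c", "e"), ("d", "e")]
PATH4 = [("a", "b"), ("b", "c"), ("c", "d")]


def brute_force_best_density(edges):
    """Exhaustively evaluate every similarity-threshold cut (networkx path)."""
    edges = [tuple(sorted(e)) for e in edges]
    sims = {}
    for e1, e2 in itertools.combinations(edges, 2):
        sims[(e1, e2)] = comm.edge_similarity(edges, e1, e2)
    thresholds = sorted(set(sims.values()), reverse=True)
    best = 0.0  # all-singletons baseline
    for t in thresholds:
        g = nx.Graph()
        g.add_nodes_from(edges)
        g.add_edges_from(pair for pair, s in sims.items() if s >= t)
        partition = [set(c) for c in nx.connected_components(g)]
        best = max(best, comm.partition_density(partition, len(edges)))
    return best


class TestEdgeSimilarity:
    def test_triangle_edges_fully_similar(self):
        assert comm.edge_similarity(TRIANGLE, ("a", "b"), ("a", "c")) == pytest.approx(1.0)

    def test_disjoint_edges_zero(self):
        assert comm.edge_similarity([("a", "b"), ("c", "d")], ("a", "b"), ("c", "d")) == 0.0

    def test_path_hand_enumeration(self):
        # path a-b-c-d: n+(a)={a,b}, n+(c)={b,c,d}; intersection {b}, union {a,b,c,d}
        assert comm.edge_similarity(PATH4, ("a", "b"), ("b", "c")) == pytest.approx(0.25)

    def test_symmetric_and_bounded(self):
        edges = BOWTIE
        for e1, e2 in itertools.combinations(edges, 2):
            s12 = comm.edge_similarity(edges, e1, e2)
            s21 = comm.edge_similarity(edges, e2, e1)
            assert s12 == s21
            assert 0.0 <= s12 <= 1.0

    def test_unknown_edge_rejected(self):
        with pytest.raises(ValueError, match="not in network"):
            comm.edge_similarity(TRIANGLE, ("a", "b"), ("a", "z"))


class TestClusterEdges:
    def test_triangle_merges_at_similarity_one(self):
        dendro = comm.cluster_edges(TRIANGLE)
        assert len(dendro.merges) == 2
        assert all(s == pytest.approx(1.0) for _, _, s in dendro.merges)

    def test_two_triangles_merge_within_then_across_at_zero(self):
        dendro = comm.cluster_edges(TWO_TRIANGLES)
        sims = [s for _, _, s in dendro.merges]
        assert sims == sorted(sims, reverse=True)
        assert sims.count(0.0) == 1  # single cross-component merge at zero

    def test_matches_brute_force_single_linkage_heights(self, rng):
        """Merge heights equal a quadratic scipy single-linkage recomputation."""
        from scipy.cluster.hierarchy import linkage

        g = nx.gnm_random_graph(8, 12, seed=5)
        edges = [tuple(sorted((str(u), str(v)))) for u, v in g.edges()]
        dendro = comm.cluster_edges(edges)
        m = len(edges)
        dist = np.zeros((m, m))
        for i, j in itertools.combinations(range(m), 2):
            s = comm.edge_similarity(edges, edges[i], edges[j])
            dist[i, j] = dist[j, i] = 1.0 - s
        z = linkage(dist[np.triu_indices(m, k=1)], method="single")
        expected_heights = sorted(1.0 - z[:, 2], reverse=True)
        got_heights = sorted((s for _, _, s in dendro.merges), reverse=True)
        np.testing.assert_allclose(got_heights, expected_heights, atol=1e-12)

    def test_single_edge_trivial_dendrogram(self):
        dendro = comm.cluster_edges([("a", "b")])
        assert dendro.merges == []


class TestPartitionDensity:
    def test_clique_attains_one(self):
        k4 = [tuple(sorted(e)) for e in itertools.combinations("abcd", 2)]
        assert comm.partition_density([set(k4)], 6) == pytest.approx(1.0)

    def test_singleton_partition_is_zero(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d")]
        assert comm.partition_density([{e} for e in edges], 3) == 0.0

    def test_two_disjoint_triangles_direct_formula(self):
        t1 = set(TRIANGLE)
        t2 = {("x", "y"), ("x", "z"), ("y", "z")}
        assert comm.partition_density([t1, t2], 6) == pytest.approx(1.0)

    def test_overlapping_communities_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            comm.partition_density([{("a", "b")}, {("a", "b"), ("b", "c")}], 2)


class TestCutAtMaxDensity:
    def test_two_triangles_give_two_communities(self):
        cs = comm.cut_at_max_density(comm.cluster_edges(TWO_TRIANGLES))
        assert len(cs.communities) == 2
        assert cs.density == pytest.approx(1.0)
        assert {frozenset({"a", "b", "c"}), frozenset({"x", "y", "z"})} == {
            frozenset(itertools.chain.from_iterable(c)) for c in cs.communities
        }

    def test_star_best_density_zero_highest_cut(self):
        cs = comm.cut_at_max_density(comm.cluster_edges(STAR))
        assert cs.density == pytest.approx(0.0)
        # tie rule: the highest-similarity (most-singleton) cut is kept
        assert len(cs.communities) == len(STAR)

    @pytest.mark.parametrize(
        "edges",
        [TRIANGLE, TWO_TRIANGLES, STAR, BOWTIE, PATH4],
        ids=["triangle", "two-triangles", "star", "bowtie", "path"],
    )
    def test_equals_exhaustive_enumeration(self, edges):
        cs = comm.cut_at_max_density(comm.cluster_edges(edges))
        assert cs.density == pytest.approx(brute_force_best_density(edges), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_graphs_equal_exhaustive_enumeration(self, seed):
        g = nx.gnm_random_graph(7, 11, seed=seed)
        edges = [tuple(sorted((str(u), str(v)))) for u, v in g.edges()]
        cs = comm.cut_at_max_density(comm.cluster_edges(edges))
        assert cs.density == pytest.approx(brute_force_best_density(edges), abs=1e-12)
        assert cs.density >= 0.0

    def test_membership_counts_consistent(self):
        cs = comm.cut_at_max_density(comm.cluster_edges(BOWTIE))
        for node in cs.nodes:
            expected = sum(
                any(node in e for e in community) for community in cs.communities
            )
            assert comm.community_centrality(cs, node) == expected


class TestCentralityAndAssembly:
    def test_bowtie_center_belongs_to_two_communities(self):
        cs = comm.cut_at_max_density(comm.cluster_edges(BOWTIE))
        assert comm.community_centrality(cs, "c") == 2
        assert comm.community_centrality(cs, "a") == 1

    def test_unknown_node_rejected(self):
        cs = comm.cut_at_max_density(comm.cluster_edges(TRIANGLE))
        with pytest.raises(KeyError):
            comm.community_centrality(cs, "nope")

    def test_butter_chain_central_by_weighted_degree(self):
        """3-node chain: the shared hub wins the |rho| tie-break."""
        from dietnet import ggm

        omega = np.eye(3)
        # Butter(0)-Animal fat(1) and Butter(0)-Margarine(2)
        omega[0, 1] = omega[1, 0] = -0.03
        omega[0, 2] = omega[2, 0] = -0.06
        partials = ggm.precision_to_partial(omega, ["Butter", "Animal fat", "Margarine"])
        cs = comm.cut_at_max_density(comm.cluster_edges(partials))
        nets = comm.assemble_networks(cs, partials)
        assert len(nets) == 1
        assert nets[0].central == ["Butter"]
        assert sorted(nets[0].nodes) == ["Animal fat", "Butter", "Margarine"]

    def test_small_components_dropped(self):
        edges = [("a", "b")] + [("p", "q"), ("q", "r"), ("r", "s"), ("s", "p")]
        cs = comm.cut_at_max_density(comm.cluster_edges(edges))
        nets = comm.assemble_networks(cs)
        assert len(nets) == 1
        assert sorted(nets[0].nodes) == ["p", "q", "r", "s"]

    def test_empty_community_set(self):
        cs = comm.LinkCommunitySet([], [], 1.0, 0.0)
        assert comm.assemble_networks(cs) == []
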