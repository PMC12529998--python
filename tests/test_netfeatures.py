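import numpy as np
import pytest

from ginet.errors import ConfigError, DataError
from ginet.graph_io import Network
from ginet.netfeatures import (
    build_pair_features,
    common_neighbors,
    compute_node_profiles,
    detect_communities,
    feature_columns,
    pairwise_connectivity,
    pairwise_shortest_path,
)
from ginet.synthetic import generate_oracle_graphs

from .oracles import (
    adjacency,
    betweenness_enumeration,
    bfs_distances,
    coreness_peeling,
    min_edge_cut_bruteforce,
)


@pytest.fixture(scope="module")
def oracle_family():
    return generate_oracle_graphs(seed=7, n_graphs=30, max_nodes=10)


class TestNodeProfiles:
    def test_triangle_k3(self):
        net = Network.from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        prof = compute_node_profiles(net)
        assert (prof["degree"] == 2).all()
        assert (prof["triangle"] == 1).all()
        assert (prof["betweenness"] == 0).all()
        assert (prof["coreness"] == 2).all()

    def test_star_center_betweenness(self):
        net = Network.from_edges([("c", "x"), ("c", "y"), ("c", "z")])
        prof = compute_node_profiles(net)
        # all 3 leaf pairs route through the center
        assert prof.at["c", "betweenness"] == 3.0
        assert prof.at["x", "betweenness"] == 0.0

    def test_path_neighborhood_and_eccentricity(self):
        net = Network.from_edges([("A", "B"), ("B", "C")])
        prof = compute_node_profiles(net)
        assert prof.at["A", "neighbor2"] == 2
        assert prof.at["A", "eccentricity"] == pytest.approx(0.5)
        raw = compute_node_profiles(net, eccentricity_mode="raw")
        assert raw.at["A", "eccentricity"] == 2

    def test_neighborhood_monotone_and_bounded(self, oracle_family):
        for net in oracle_family[:10]:
            prof = compute_node_profiles(net)
            assert (prof["neighbor1"] == prof["degree"]).all()
            assert (prof["neighbor1"] <= prof["neighbor2"]).all()
            assert (prof["neighbor2"] <= prof["neighbor3"]).all()
            assert (prof["neighbor3"] <= net.n_nodes - 1).all()
            d = prof["degree"]
            assert (prof["triangle"] <= d * (d - 1) / 2).all()
            assert (prof["coreness"] <= d).all()

    def test_hub_score_equals_eigenvector_centrality(self, oracle_family):
        """On connected non-bipartite undirected graphs HITS hubs and
        eigencentrality coincide (elsewhere the A^2 eigenproblem is
        degenerate and the hub vector is not unique)."""
        import networkx as nx

        checked = 0
        for net in oracle_family:
            if nx.number_connected_components(net.graph) > 1 or nx.is_bipartite(net.graph):
                continue
            prof = compute_node_profiles(net)
            assert np.max(np.abs(prof["hub_score"] - prof["eigen_centrality"])) < 1e-6
            checked += 1
        assert checked >= 5

    def test_empty_network_rejected(self):
        import networkx as nx

        with pytest.raises(DataError):
            compute_node_profiles(Network(nx.Graph()))


class TestCommunities:
    def test_two_disjoint_triangles(self, two_triangles):
        comm = detect_communities(two_triangles)
        assert comm.nunique() == 2
        assert comm["A"] == comm["B"] == comm["C"]
        assert comm["X"] == comm["Y"] == comm["Z"]

    def test_single_clique_low_resolution_one_community(self):
        """At resolution 0.005 the CPM objective keeps K5 together."""
        from itertools import combinations

        net = Network.from_edges(combinations("ABCDE", 2))
        assert detect_communities(net, resolution=0.005).nunique() == 1

    def test_invalid_resolution(self, two_triangles):
        with pytest.raises(ConfigError):
            detect_communities(two_triangles, resolution=0.0)

    def test_seed_reproducible(self, benchmark):
        a = detect_communities(benchmark.network, seed=5)
        b = detect_communities(benchmark.network, seed=5)
        assert (a == b).all()


class TestPairwiseOps:
    def test_path_endpoints(self, path4):
        assert pairwise_shortest_path(path4, "A", "D") == 3
        assert pairwise_shortest_path(path4, "A", "B") == 1

    def test_diameter_substitution_for_disconnected_pair(self):
        net = Network.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("E", "F")])
        assert pairwise_shortest_path(net, "A", "E") == 3  # finite diameter of the path

    def test_unknown_gene(self, path4):
        with pytest.raises(DataError):
            pairwise_shortest_path(path4, "A", "Q")

    def test_connectivity_p3(self):
        net = Network.from_edges([("A", "B"), ("B", "C")])
        assert pairwise_connectivity(net, "A", "C") == (1, 1)

    def test_connectivity_k4_adjacent_convention(self, k4):
        assert pairwise_connectivity(k4, "A", "B") == (3, 3)

    def test_connectivity_disconnected_pair(self):
        net = Network.from_edges([("A", "B"), ("C", "D")])
        assert pairwise_connectivity(net, "A", "C") == (0, 0)

    def test_single_edge_pair(self):
        net = Network.from_edges([("A", "B")])
        assert pairwise_connectivity(net, "A", "B") == (1, 1)

    @pytest.mark.parametrize(
        "edges, pair, expected",
        [
            ([("A", "B"), ("B", "C"), ("C", "A")], ("A", "B"), 1),
            ([("A", "B"), ("B", "C")], ("A", "C"), 1),
            ([("A", "B"), ("C", "D")], ("A", "C"), 0),
        ],
    )
    def test_common_neighbors(self, edges, pair, expected):
        assert common_neighbors(Network.from_edges(edges), *pair) == expected

    def test_adding_edge_never_lengthens_paths_or_cuts(self, oracle_family):
        """Monotonicity: a new edge can only shorten geodesics and fatten cuts."""
        rng = np.random.default_rng(0)
        for net in oracle_family[:8]:
            nodes = sorted(net.nodes)
            if len(nodes) < 4:
                continue
            a, b = [nodes[i] for i in rng.choice(len(nodes), 2, replace=False)]
            if b in net.neighbors(a):
                continue
            g2 = net.graph.copy()
            g2.add_edge(a, b)
            net2 = Network(g2)
            for u in nodes:
                d1 = bfs_distances(adjacency(net), u)
                d2 = bfs_distances(adjacency(net2), u)
                for v, dv in d1.items():
                    assert d2[v] <= dv
            _, adh1 = pairwise_connectivity(net, a, b)
            _, adh2 = pairwise_connectivity(net2, a, b)
            assert adh2 >= adh1


class TestOracleEquivalence:
    """Implementation vs naive enumeration on small seeded random graphs."""

    def test_betweenness_matches_enumeration(self, oracle_family):
        for net in oracle_family:
            prof = compute_node_profiles(net)
            oracle = betweenness_enumeration(adjacency(net))
            for v in net.nodes:
                assert prof.at[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)

    def test_coreness_matches_peeling(self, oracle_family):
        for net in oracle_family:
            prof = compute_node_profiles(net)
            oracle = coreness_peeling(adjacency(net))
            for v in net.nodes:
                assert prof.at[v, "coreness"] == oracle[v]

    def test_adhesion_matches_exhaustive_cuts(self, oracle_family):
        rng = np.random.default_rng(3)
        for net in oracle_family[:12]:
            nodes = sorted(net.nodes)
            for _ in range(4):
                a, b = [nodes[i] for i in rng.choice(len(nodes), 2, replace=False)]
                _, adhesion = pairwise_connectivity(net, a, b)
                assert adhesion == min_edge_cut_bruteforce(adjacency(net), a, b)


class TestBuildPairFeatures:
    def test_degree_averaging_rule(self):
        # star(a, 4 leaves) plus path through b: degree(a)=4, degree(b)=2
        net = Network.from_edges(
            [("a", "x1"), ("a", "x2"), ("a", "x3"), ("a", "b"), ("b", "c")]
        )
        row = build_pair_features(net, [("a", "b")]).iloc[0]
        assert row["avg_degree"] == pytest.approx(3.0)

    def test_symmetry_under_pair_swap(self, k4):
        feats = build_pair_features(k4, [("A", "B"), ("B", "A")])
        a, b = feats.iloc[0], feats.iloc[1]
        assert (a == b).all()

    @pytest.mark.parametrize("agg", ["sum", "diff", "max", "min"])
    def test_alternative_aggregations_stay_symmetric(self, k4, agg):
        feats = build_pair_features(k4, [("A", "C"), ("C", "A")], aggregation=agg)
        assert (feats.iloc[0] == feats.iloc[1]).all()
        assert feature_columns(agg)[0].startswith(agg)

    def test_unmapped_pair_flagged_not_fatal(self, path4):
        feats = build_pair_features(path4, [("A", "B"), ("A", "ZZ")])
        assert feats["mapped"].tolist() == [True, False]
        assert feats.iloc[1]["shortest_path" ] != feats.iloc[1]["shortest_path"]  # NaN

    def test_pair_feature_invariants(self, benchmark_features, benchmark):
        feats = benchmark_features[benchmark_features["mapped"]]
        assert (feats["shortest_path"] <= benchmark.network.diameter_finite).all()
        assert (feats["shortest_path"] >= 1).all()
        assert feats["same_community"].isin([0, 1]).all()
        # common neighbors and adhesion are bounded by the smaller degree
        for _, row in feats.sample(40, random_state=0).iterrows():
            dmin = min(
                benchmark.network.degree(row["gene_a"]),
                benchmark.network.degree(row["gene_b"]),
            )
            assert row["common_neighbors"] <= dmin
            assert row["adhesion"] <= dmin
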