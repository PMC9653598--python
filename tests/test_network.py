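import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import anchorsig as a
from anchorsig.errors import ValidationError
from conftest import make_clique_graph


def brute_force_min_nodes(g: nx.Graph, seeds: set) -> int:
    """Independent oracle: smallest connected induced subgraph covering seeds."""
    others = sorted(set(g.nodes) - seeds)
    for size in range(len(others) + 1):
        for extra in itertools.combinations(others, size):
            if nx.is_connected(g.subgraph(seeds | set(extra))):
                return len(seeds) + size
    raise AssertionError("seeds not connectable")


class TestMinimumOrder:
    def test_path_graph_unique_connector(self):
        g = a.InteractionGraph.from_edges([("a", "b"), ("b", "c")])
        net = a.minimum_order(g, {"a", "c"})
        assert net.seeds == ("A", "C")
        assert net.connectors == ("B",)
        assert set(net.edges) == {("A", "B"), ("B", "C")}

    def test_adjacent_seeds_need_no_connectors(self):
        g = a.InteractionGraph.from_edges([("a", "b"), ("b", "c")])
        net = a.minimum_order(g, {"a", "b"})
        assert net.connectors == ()

    def test_star_graph_selects_exactly_the_center(self):
        g = a.InteractionGraph.from_edges(
            [("H", s) for s in ("S1", "S2", "S3", "S4")]
        )
        net = a.minimum_order(g, {"S1", "S2", "S3", "S4"})
        assert net.connectors == ("H",)
        assert len(net.edges) == 4

    def test_absent_seeds_dropped_with_warning(self):
        g = a.InteractionGraph.from_edges([("a", "b")])
        with pytest.warns(UserWarning, match="absent"):
            net = a.minimum_order(g, {"a", "b", "zz"})
        assert net.dropped_seeds == ("ZZ",)

    def test_fewer_than_two_in_graph_seeds_rejected(self):
        g = a.InteractionGraph.from_edges([("a", "b")])
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError):
                a.minimum_order(g, {"a", "zz"})

    def test_seed_alone_in_component_reported_isolated(self):
        g = a.InteractionGraph.from_edges([("a", "b"), ("x", "y")])
        net = a.minimum_order(g, {"a", "b", "x"})
        assert net.isolated_seeds == ("X",)
        assert net.nodes == {"A", "B"}

    def test_matches_bruteforce_on_small_random_graphs(self):
        rng = np.random.default_rng(5)
        done = 0
        while done < 120:
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2 ** 31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            seeds = set(rng.choice(sorted(g.nodes), int(rng.integers(2, 5)),
                                   replace=False))
            if not any(seeds <= c for c in nx.connected_components(g)):
                continue
            net = a.minimum_order(a.InteractionGraph(g), seeds)
            got = len(net.seeds) + len(net.connectors)
            assert got == brute_force_min_nodes(g, seeds)
            done += 1

    def test_heuristic_branch_on_long_path(self):
        # > EXACT_CANDIDATE_LIMIT candidates forces the shortest-path heuristic
        chain = [(f"N{i:02d}", f"N{i + 1:02d}") for i in range(20)]
        g = a.InteractionGraph.from_edges(chain)
        net = a.minimum_order(g, {"N00", "N20"})
        assert len(net.connectors) == 19  # the whole interior of the path

    def test_connectors_lie_on_seed_paths(self):
        g = make_clique_graph((5, 5), p_background=0.2, seed=3)
        nodes = sorted(g.nodes)
        net = a.minimum_order(g, {nodes[0], nodes[4], nodes[9]})
        sub = nx.Graph(list(net.edges))
        sub.add_nodes_from(net.nodes)
        for c in net.connectors:
            trimmed = sub.copy()
            trimmed.remove_node(c)
            # removing any connector must disconnect some pair of seeds
            seeds_in = [s for s in net.seeds if s in trimmed]
            assert not all(
                nx.has_path(trimmed, s, t)
                for s, t in itertools.combinations(seeds_in, 2)
            )


class TestGraphKmeans:
    def test_planted_cliques_recovered(self):
        g = make_clique_graph((4, 4, 4, 4))
        prots = sorted(g.nodes)
        cl = a.graph_kmeans(g, prots, k=4, seed=0)
        truth = [(int(p[1:]) - 1) // 4 for p in prots]
        assert adjusted_rand_score(truth, [cl.labels[p] for p in prots]) == 1.0

    def test_k_one_and_k_equal_m(self):
        g = make_clique_graph((4, 4))
        prots = sorted(g.nodes)
        assert set(a.graph_kmeans(g, prots, k=1, seed=0).labels.values()) == {0}
        singletons = a.graph_kmeans(g, prots, k=len(prots), seed=0)
        assert sorted(singletons.labels.values()) == list(range(len(prots)))

    def test_k_beyond_protein_count_rejected(self):
        g = make_clique_graph((4,))
        with pytest.raises(ValidationError, match="k"):
            a.graph_kmeans(g, sorted(g.nodes), k=5, seed=0)

    def test_missing_protein_rejected(self):
        g = make_clique_graph((4,))
        with pytest.raises(ValidationError, match="absent"):
            a.graph_kmeans(g, ["NOPE"], k=1, seed=0)

    def test_deterministic_for_fixed_seed(self):
        g = make_clique_graph((4, 4, 4), p_background=0.1, seed=2)
        prots = sorted(g.nodes)
        l1 = a.graph_kmeans(g, prots, k=3, seed=11).labels
        l2 = a.graph_kmeans(g, prots, k=3, seed=11).labels
        assert l1 == l2

    def test_labels_canonical_by_smallest_member(self):
        g = make_clique_graph((4, 4))
        prots = sorted(g.nodes)
        cl = a.graph_kmeans(g, prots, k=2, seed=0)
        assert cl.labels[prots[0]] == 0


class TestAnnotateNetwork:
    def _net(self):
        g = a.InteractionGraph.from_edges([("S1", "B"), ("B", "S2")])
        return a.minimum_order(g, {"S1", "S2"})

    def test_pvalues_identical_to_direct_ora(self):
        net = self._net()
        universe = [f"G{i}" for i in range(50)] + ["S1", "S2", "B"]
        coll = a.GeneSetCollection({"PW": frozenset({"S1", "S2", "B", "G1"})})
        ann = a.annotate_network(net, coll, universe)
        direct = a.run_ora({"S1", "S2", "B"}, coll, universe)
        assert [r.p_value for r in ann.records] == [r.p_value for r in direct]

    def test_records_flag_seed_and_connector_members(self):
        net = self._net()
        universe = [f"G{i}" for i in range(50)] + ["S1", "S2", "B"]
        coll = a.GeneSetCollection({"PW": frozenset({"S1", "S2", "B"})})
        ann = a.annotate_network(net, coll, universe)
        assert ann.seed_members["PW"] == ("S1", "S2")
        assert ann.connector_members["PW"] == ("B",)

    def test_pathway_covering_seeds_ranks_first(self):
        net = self._net()
        universe = [f"G{i}" for i in range(200)] + ["S1", "S2", "B"]
        coll = a.GeneSetCollection({
            "COVER": frozenset({"S1", "S2", "B"}),
            "NOISE": frozenset({"G1", "G2", "G3", "S1"}),
        })
        ann = a.annotate_network(net, coll, universe)
        assert ann.records[0].set_id == "COVER"

    def test_no_overlap_collection_gives_no_significant_records(self):
        net = self._net()
        universe = [f"G{i}" for i in range(50)] + ["S1", "S2", "B"]
        coll = a.GeneSetCollection({"FAR": frozenset({"G1", "G2"})})
        ann = a.annotate_network(net, coll, universe)
        assert all(not r.significant for r in ann.records)
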