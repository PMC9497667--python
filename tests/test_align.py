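"""Alignment-graph construction: pair selection, edge classification, assembly."""

import itertools
import math
import random

import networkx as nx
import pytest

from multiloal import (
    EdgeKind,
    MultilayerNetwork,
    NodeRef,
    ParameterError,
    ScoringConfig,
    SeedEntry,
    SeedMap,
    UsageError,
    build_multilayer_alignment_graph,
    degrade,
    generate_multilayer,
    GeneratorParams,
    identity_seed_map,
)
from multiloal.align import (
    PairNode,
    build_layer_alignment_graph,
    classify_intra,
    select_pair_nodes,
    write_alignment_graph,
)

INF = math.inf


def oracle_classify(d1, d2, delta):
    """Literal rule table: match both adjacent; gap/mismatch by Δ; else none."""
    if d1 == 1 and d2 == 1:
        return EdgeKind.HOM_MATCH
    if (d1 == 1) != (d2 == 1):
        far = d2 if d1 == 1 else d1
        return EdgeKind.HOM_GAP if 2 <= far <= delta else EdgeKind.HOM_MISMATCH
    return None


def two_nets_from_edges(ids, edges1, edges2, layer="L1"):
    n1, n2 = MultilayerNetwork("g1"), MultilayerNetwork("g2")
    for net, edges in ((n1, edges1), (n2, edges2)):
        for v in ids:
            net.add_node(layer, v)
        for u, v in edges:
            net.add_intra_edge(layer, u, v)
    return n1, n2


class TestClassifyIntra:
    @pytest.mark.parametrize(
        "d1, d2, delta, expected",
        [
            (1, 1, 2, EdgeKind.HOM_MATCH),
            (1, 2, 2, EdgeKind.HOM_GAP),
            (1, 3, 2, EdgeKind.HOM_MISMATCH),
            (2, 2, 2, None),
            (1, INF, 2, EdgeKind.HOM_MISMATCH),
            (1, 3, 3, EdgeKind.HOM_GAP),
        ],
    )
    def test_rule_table_examples(self, d1, d2, delta, expected):
        assert classify_intra(d1, d2, delta) == expected

    @pytest.mark.parametrize("delta", [2, 3, 5])
    def test_exhaustive_against_literal_rule(self, delta):
        distances = [1, 2, 3, 4, 5, INF]
        for d1, d2 in itertools.product(distances, repeat=2):
            assert classify_intra(d1, d2, delta) == oracle_classify(d1, d2, delta)

    def test_symmetry_in_the_two_networks(self):
        for d1, d2 in itertools.product([1, 2, 3, INF], repeat=2):
            assert classify_intra(d1, d2, 2) == classify_intra(d2, d1, 2)

    def test_small_delta_rejected(self):
        with pytest.raises(ParameterError):
            classify_intra(1, 1, 1)


class TestSelectPairNodes:
    def test_identity_seeds_pair_every_node_with_itself(self, n1_net):
        pairs = select_pair_nodes(identity_seed_map(n1_net), n1_net, n1_net)
        for layer in n1_net.layers:
            assert {(p.u, p.v) for p in pairs[layer]} == {
                (v, v) for v in n1_net.nodes[layer]
            }

    def test_greedy_best_similarity_rule(self):
        net1, net2 = two_nets_from_edges(["a", "b", "x", "y"], [], [])
        seeds = SeedMap(
            [
                SeedEntry("L1", "a", "x", 0.9),
                SeedEntry("L1", "a", "y", 0.8),
                SeedEntry("L1", "b", "y", 0.7),
            ]
        )
        pairs = select_pair_nodes(seeds, net1, net2)
        assert {(p.u, p.v) for p in pairs["L1"]} == {("a", "x"), ("b", "y")}

    def test_equal_similarity_tie_break_is_lexicographic(self):
        net1, net2 = two_nets_from_edges(["a", "b", "x"], [], [])
        seeds = SeedMap(
            [SeedEntry("L1", "b", "x", 0.5), SeedEntry("L1", "a", "x", 0.5)]
        )
        pairs = select_pair_nodes(seeds, net1, net2)
        assert {(p.u, p.v) for p in pairs["L1"]} == {("a", "x")}


class TestLayerGraph:
    def test_path_versus_single_edge_instance(self):
        # net1 path a-b-c, net2 only a-b: traced by hand against the rule table
        net1, net2 = two_nets_from_edges(
            ["a", "b", "c"], [("a", "b"), ("b", "c")], [("a", "b")]
        )
        pairs = [PairNode("L1", v, v) for v in "abc"]
        edges = build_layer_alignment_graph("L1", pairs, net1, net2, ScoringConfig())
        kinds = {
            (e.p.u, e.q.u): e.kind for e in edges
        }
        assert kinds == {
            ("a", "b"): EdgeKind.HOM_MATCH,
            ("b", "c"): EdgeKind.HOM_MISMATCH,  # dist in net2 is infinite
        }

    def test_empty_layer_yields_no_edges(self):
        net1, net2 = two_nets_from_edges(["a"], [], [])
        assert build_layer_alignment_graph("L1", [], net1, net2, ScoringConfig()) == set()

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_oracle_on_random_instances(self, trial):
        """Edge kinds equal a full-BFS oracle applying the rule table literally."""
        rng = random.Random(1000 + trial)
        n = rng.randint(2, 12)
        ids = [f"x{i}" for i in range(n)]
        def rand_edges():
            p = rng.uniform(0.1, 0.5)
            return [
                (u, v) for u, v in itertools.combinations(ids, 2) if rng.random() < p
            ]
        net1, net2 = two_nets_from_edges(ids, rand_edges(), rand_edges())
        perm = ids[:]
        rng.shuffle(perm)
        pairs = [PairNode("L1", u, v) for u, v in zip(ids, perm)]
        cfg = ScoringConfig(delta=rng.choice([2, 3]))

        g1, g2 = net1.layer_graph("L1"), net2.layer_graph("L1")
        d1 = dict(nx.all_pairs_shortest_path_length(g1))
        d2 = dict(nx.all_pairs_shortest_path_length(g2))
        expected = {}
        for p, q in itertools.combinations(sorted(pairs), 2):
            kind = oracle_classify(
                d1[p.u].get(q.u, INF), d2[p.v].get(q.v, INF), cfg.delta
            )
            if kind:
                expected[(p.key, q.key)] = kind

        got = {
            (e.p.key, e.q.key): e.kind
            for e in build_layer_alignment_graph("L1", pairs, net1, net2, cfg)
        }
        assert got == expected


class TestInterlayerEdges:
    def test_missing_edge_in_one_network_is_het_mismatch(self, tiny_net):
        other = tiny_net.copy("degraded")
        other.inter_edges.clear()
        graph = build_multilayer_alignment_graph(
            tiny_net, other, identity_seed_map(tiny_net)
        )
        het = [e for e in graph.edges if not e.kind.is_intra]
        assert len(het) == 1
        assert het[0].kind == EdgeKind.HET_MISMATCH and het[0].weight == 0.4

    def test_edge_in_neither_network_yields_nothing(self, tiny_net):
        bare = tiny_net.copy()
        bare.inter_edges.clear()
        graph = build_multilayer_alignment_graph(bare, bare, identity_seed_map(bare))
        assert all(e.kind.is_intra for e in graph.edges)


class TestFullGraph:
    def test_self_alignment_is_isomorphic_with_match_edges_only(self, n1_net):
        graph = build_multilayer_alignment_graph(
            n1_net, n1_net, identity_seed_map(n1_net)
        )
        counts = graph.kind_counts()
        assert counts[EdgeKind.HOM_MATCH] == n1_net.n_intra_edges
        assert counts[EdgeKind.HET_MATCH] == len(n1_net.inter_edges)
        assert len(graph.edges) == n1_net.n_edges
        assert graph.n_pair_nodes == n1_net.n_nodes

    def test_match_counts_equal_surviving_edges_after_degradation(self, n1_net):
        noisy = degrade(n1_net, 0.25, seed=4)
        graph = build_multilayer_alignment_graph(
            n1_net, noisy, identity_seed_map(n1_net)
        )
        counts = graph.kind_counts()
        assert counts[EdgeKind.HOM_MATCH] == noisy.n_intra_edges
        assert counts[EdgeKind.HET_MATCH] == len(noisy.inter_edges)

    def test_match_counts_never_increase_as_noise_rises(self, n1_net):
        seeds = identity_seed_map(n1_net)
        matches = []
        for noise in (0.0, 0.1, 0.2, 0.3):
            noisy = degrade(n1_net, noise, seed=8)
            counts = build_multilayer_alignment_graph(
                n1_net, noisy, seeds
            ).kind_counts()
            matches.append(counts[EdgeKind.HOM_MATCH] + counts[EdgeKind.HET_MATCH])
        assert matches == sorted(matches, reverse=True)

    def test_weight_discipline(self):
        net = generate_multilayer(GeneratorParams(20, 2, 40, 0.3, seed=13))
        noisy = degrade(net, 0.3, seed=14)
        cfg = ScoringConfig()
        graph = build_multilayer_alignment_graph(
            net, noisy, identity_seed_map(net), cfg
        )
        allowed = {cfg.w_match, cfg.w_mismatch, cfg.w_gap, cfg.w_het_match, cfg.w_het_mismatch}
        assert graph.edges and {e.weight for e in graph.edges} <= allowed

    def test_disjoint_layer_labels_rejected(self):
        a, b = MultilayerNetwork(), MultilayerNetwork()
        a.add_node("L1", "x")
        b.add_node("M1", "x")
        with pytest.raises(UsageError):
            build_multilayer_alignment_graph(a, b, SeedMap([]))

    def test_one_sided_layer_skipped_with_warning(self, tiny_net, caplog):
        wider = tiny_net.copy()
        wider.add_node("L3", "z")
        with caplog.at_level("WARNING"):
            graph = build_multilayer_alignment_graph(
                wider, tiny_net, identity_seed_map(tiny_net)
            )
        assert graph.layers == ["L1", "L2"]
        assert any("L3" in r.message for r in caplog.records)

    def test_export_is_deterministic(self, tmp_path, n1_net):
        graph = build_multilayer_alignment_graph(
            n1_net, n1_net, identity_seed_map(n1_net)
        )
        p1, p2 = tmp_path / "g1.tsv", tmp_path / "g2.tsv"
        write_alignment_graph(graph, p1)
        write_alignment_graph(graph, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_text().startswith("#multiloal-aligngraph v1\n")
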