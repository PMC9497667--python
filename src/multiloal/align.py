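"""Construction of the weighted multilayer alignment graph.

Each vertex of the alignment graph is a *pair node* (u, v): one node from
each input network, in the same layer, matched through the seed
similarities.  Edges encode the joint adjacency of the two members:

* intra-layer — members adjacent in both inputs (match, weight ``w_match``),
  adjacent in one and within Δ hops in the other (gap, ``w_gap``), or
  adjacent in one and farther than Δ / disconnected in the other
  (mismatch, ``w_mismatch``);
* inter-layer — the corresponding inter-layer edge present in both inputs
  (heterogeneous match, ``w_het_match``) or in exactly one
  (heterogeneous mismatch, ``w_het_mismatch``).

Communities of this graph are the local alignments.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx

from .errors import ParameterError, UsageError
from .model import MultilayerNetwork, NodeRef, ScoringConfig, SeedMap

logger = logging.getLogger(__name__)

INF = math.inf


class EdgeKind(str, Enum):
    HOM_MATCH = "homogeneous match"
    HOM_MISMATCH = "homogeneous mismatch"
    HOM_GAP = "homogeneous gap"
    HET_MATCH = "heterogeneous match"
    HET_MISMATCH = "heterogeneous mismatch"

    @property
    def is_intra(self) -> bool:
        return self in (EdgeKind.HOM_MATCH, EdgeKind.HOM_MISMATCH, EdgeKind.HOM_GAP)


@dataclass(frozen=True, order=True)
class PairNode:
    """One alignment-graph vertex: node *u* of network 1 matched to *v* of network 2."""

    layer: str
    u: str
    v: str
    similarity: float = 1.0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.layer, self.u, self.v)


@dataclass(frozen=True)
class AlignmentEdge:
    """Undirected, kind-labelled, weighted edge between two pair nodes."""

    p: PairNode
    q: PairNode
    kind: EdgeKind
    weight: float

    def __post_init__(self) -> None:
        if self.p.key > self.q.key:  # normalise orientation
            p, q = self.p, self.q
            object.__setattr__(self, "p", q)
            object.__setattr__(self, "q", p)

    @property
    def endpoints(self) -> tuple[PairNode, PairNode]:
        return (self.p, self.q)


def _normalised_edge(p: PairNode, q: PairNode, kind: EdgeKind, weight: float) -> AlignmentEdge:
    if p.key > q.key:
        p, q = q, p
    return AlignmentEdge(p, q, kind, weight)


@dataclass
class MultilayerAlignmentGraph:
    """The merged alignment graph: pair nodes per layer plus labelled edges."""

    layers: list[str] = field(default_factory=list)
    pair_nodes: dict[str, list[PairNode]] = field(default_factory=dict)
    edges: set[AlignmentEdge] = field(default_factory=set)

    @property
    def n_pair_nodes(self) -> int:
        return sum(len(v) for v in self.pair_nodes.values())

    def all_pair_nodes(self) -> list[PairNode]:
        return [p for layer in self.layers for p in self.pair_nodes[layer]]

    def kind_counts(self) -> dict[EdgeKind, int]:
        counts = {kind: 0 for kind in EdgeKind}
        for e in self.edges:
            counts[e.kind] += 1
        return counts

    def to_networkx(self) -> nx.Graph:
        """Flatten to a simple weighted graph over pair-node vertices.

        Pair nodes are distinct per layer, so the multilayer alignment graph
        is already simple; community miners operate on this view.
        """
        g = nx.Graph()
        for p in self.all_pair_nodes():
            g.add_node(p)
        for e in self.edges:
            g.add_edge(e.p, e.q, weight=e.weight, kind=e.kind)
        return g


def select_pair_nodes(
    seeds: SeedMap,
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
) -> dict[str, list[PairNode]]:
    """Greedy best-similarity one-to-one matching of seed pairs, per layer.

    Entries are taken in order of similarity (descending), ties broken by
    (id1, id2) ascending; an entry is accepted iff neither endpoint is
    already matched in that layer.  Deterministic by construction.
    """
    seeds.validate(net1, net2)
    out: dict[str, list[PairNode]] = {}
    for layer, entries in sorted(seeds.by_layer().items()):
        taken_u: set[str] = set()
        taken_v: set[str] = set()
        chosen: list[PairNode] = []
        for e in sorted(entries, key=lambda e: (-e.similarity, e.id1, e.id2)):
            if e.id1 in taken_u or e.id2 in taken_v:
                continue
            taken_u.add(e.id1)
            taken_v.add(e.id2)
            chosen.append(PairNode(layer, e.id1, e.id2, e.similarity))
        out[layer] = sorted(chosen)
    return out


def classify_intra(d1: float, d2: float, delta: int) -> EdgeKind | None:
    """Classify an intra-layer candidate edge from the two member distances.

    ``d1``/``d2`` are hop distances between the member nodes in network 1 /
    network 2 (``math.inf`` if disconnected).  Match: adjacent in both.
    Gap: adjacent in one, within [2, delta] in the other.  Mismatch:
    adjacent in one, beyond delta (or disconnected) in the other.
    Otherwise no edge.
    """
    if delta < 2:
        raise ParameterError("delta must be >= 2")
    adj1, adj2 = d1 == 1, d2 == 1
    if adj1 and adj2:
        return EdgeKind.HOM_MATCH
    if adj1 != adj2:
        other = d2 if adj1 else d1
        if 2 <= other <= delta:
            return EdgeKind.HOM_GAP
        return EdgeKind.HOM_MISMATCH
    return None


def _bounded_distances(
    graph: nx.Graph, sources: list[str], cutoff: int
) -> dict[str, dict[str, int]]:
    """Exact hop distances up to *cutoff* from each source; absent => beyond."""
    return {
        s: nx.single_source_shortest_path_length(graph, s, cutoff=cutoff)
        for s in sources
        if s in graph
    }


def build_layer_alignment_graph(
    layer: str,
    pair_nodes: list[PairNode],
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
    cfg: ScoringConfig,
) -> set[AlignmentEdge]:
    """Intra-layer alignment edges for one layer (all-pairs over pair nodes).

    Distances are computed on the layer's intra-edge graphs only, by
    per-source BFS truncated at Δ — distances beyond Δ are
    indistinguishable from disconnection for classification.
    """
    weight_of = {
        EdgeKind.HOM_MATCH: cfg.w_match,
        EdgeKind.HOM_MISMATCH: cfg.w_mismatch,
        EdgeKind.HOM_GAP: cfg.w_gap,
    }
    g1 = net1.layer_graph(layer)
    g2 = net2.layer_graph(layer)
    d1 = _bounded_distances(g1, [p.u for p in pair_nodes], cfg.delta)
    d2 = _bounded_distances(g2, [p.v for p in pair_nodes], cfg.delta)

    edges: set[AlignmentEdge] = set()
    for p, q in itertools.combinations(sorted(pair_nodes), 2):
        if p.u == q.u or p.v == q.v:  # defensive; one-to-one pairing forbids this
            continue
        dist1 = d1.get(p.u, {}).get(q.u, INF)
        dist2 = d2.get(p.v, {}).get(q.v, INF)
        kind = classify_intra(dist1, dist2, cfg.delta)
        if kind is not None:
            edges.add(_normalised_edge(p, q, kind, weight_of[kind]))
    return edges


def add_interlayer_edges(
    pair_nodes: dict[str, list[PairNode]],
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
    cfg: ScoringConfig,
) -> set[AlignmentEdge]:
    """Inter-layer alignment edges across every pair of layers.

    For pair nodes p=(u1,v1)@k and q=(u2,v2)@h, the inter-layer edge
    (u1@k, u2@h) of network 1 and (v1@k, v2@h) of network 2 decide the kind:
    both present => heterogeneous match; exactly one => heterogeneous
    mismatch; neither => no edge.
    """
    edges: set[AlignmentEdge] = set()
    layers = sorted(pair_nodes)
    for la, lb in itertools.combinations(layers, 2):
        for p in pair_nodes[la]:
            for q in pair_nodes[lb]:
                e1 = net1.has_inter_edge(NodeRef(la, p.u), NodeRef(lb, q.u))
                e2 = net2.has_inter_edge(NodeRef(la, p.v), NodeRef(lb, q.v))
                if e1 and e2:
                    edges.add(
                        _normalised_edge(p, q, EdgeKind.HET_MATCH, cfg.w_het_match)
                    )
                elif e1 != e2:
                    edges.add(
                        _normalised_edge(
                            p, q, EdgeKind.HET_MISMATCH, cfg.w_het_mismatch
                        )
                    )
    return edges


def build_multilayer_alignment_graph(
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
    seeds: SeedMap,
    cfg: ScoringConfig | None = None,
) -> MultilayerAlignmentGraph:
    """Full pipeline: pair-node selection, intra-layer edges, inter-layer edges.

    Layers are matched across the two networks by identifier; layers present
    in only one network are skipped with a warning.
    """
    cfg = cfg or ScoringConfig()
    common = [layer for layer in net1.layers if layer in net2.nodes]
    skipped = (set(net1.layers) | set(net2.layers)) - set(common)
    if not common:
        raise UsageError("the two networks share no layer identifiers")
    for layer in sorted(skipped):
        logger.warning("layer %r present in only one network; skipped", layer)

    pair_nodes = select_pair_nodes(seeds, net1, net2)
    pair_nodes = {layer: pair_nodes.get(layer, []) for layer in common}

    graph = MultilayerAlignmentGraph(layers=list(common), pair_nodes=pair_nodes)
    for layer in common:
        graph.edges |= build_layer_alignment_graph(
            layer, pair_nodes[layer], net1, net2, cfg
        )
    graph.edges |= add_interlayer_edges(pair_nodes, net1, net2, cfg)
    counts = graph.kind_counts()
    logger.info(
        "alignment graph: %d pair nodes, %s",
        graph.n_pair_nodes,
        ", ".join(f"{k.value}={n}" for k, n in counts.items() if n),
    )
    return graph


ALIGNGRAPH_HEADER = "#multiloal-aligngraph v1"


def write_alignment_graph(graph: MultilayerAlignmentGraph, path: str | Path) -> None:
    """Export in the alignment-graph TSV dialect (node lines, then edge lines)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(ALIGNGRAPH_HEADER + "\n")
        for p in sorted(graph.all_pair_nodes()):
            fh.write(f"N\t{p.layer}\t{p.u}|{p.v}\t{p.similarity:g}\n")
        lines = [
            f"E\t{e.p.layer}\t{e.p.u}|{e.p.v}\t{e.q.layer}\t{e.q.u}|{e.q.v}"
            f"\t{e.kind.name}\t{e.weight:g}"
            for e in graph.edges
        ]
        for line in sorted(lines):
            fh.write(line + "\n")
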