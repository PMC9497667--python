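"""Core data model: multilayer networks, seed similarity maps, scoring weights.

A multilayer network is a set of layers, each an undirected simple graph over
its own node namespace, plus a set of undirected inter-layer edges joining
nodes of two different layers.  The same node id may appear in two layers and
denotes two distinct nodes; identity across layers is never assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import networkx as nx

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)


class NodeRef(NamedTuple):
    """A node addressed by (layer, id)."""

    layer: str
    id: str


#: An intra-layer edge, endpoints sorted lexicographically.
IntraEdge = tuple[str, str]
#: An inter-layer edge, NodeRef endpoints sorted by (layer, id).
InterEdge = tuple[NodeRef, NodeRef]


def intra_edge(u: str, v: str) -> IntraEdge:
    """Normalise an undirected intra-layer edge; rejects self-loops."""
    if u == v:
        raise ValidationError(f"self-loop on node {u!r}")
    return (u, v) if u < v else (v, u)


def inter_edge(a: NodeRef, b: NodeRef) -> InterEdge:
    """Normalise an undirected inter-layer edge; endpoints must differ in layer."""
    if a.layer == b.layer:
        raise ValidationError(
            f"inter-layer edge within one layer: {a} -- {b}"
        )
    return (a, b) if a <= b else (b, a)


@dataclass
class MultilayerNetwork:
    """A validated multilayer graph (layers, per-layer nodes/edges, inter edges)."""

    name: str = ""
    layers: list[str] = field(default_factory=list)
    nodes: dict[str, set[str]] = field(default_factory=dict)
    intra_edges: dict[str, set[IntraEdge]] = field(default_factory=dict)
    inter_edges: set[InterEdge] = field(default_factory=set)

    # -- construction helpers -------------------------------------------------

    def add_layer(self, layer: str) -> None:
        if not layer:
            raise ValidationError("layer identifier must be non-empty")
        if layer not in self.nodes:
            self.layers.append(layer)
            self.nodes[layer] = set()
            self.intra_edges[layer] = set()

    def add_node(self, layer: str, node_id: str) -> None:
        if not node_id:
            raise ValidationError("node id must be non-empty")
        self.add_layer(layer)
        self.nodes[layer].add(node_id)

    def add_intra_edge(self, layer: str, u: str, v: str) -> bool:
        """Add edge (u, v) in *layer*; returns False if it was already present."""
        self.add_node(layer, u)
        self.add_node(layer, v)
        e = intra_edge(u, v)
        if e in self.intra_edges[layer]:
            return False
        self.intra_edges[layer].add(e)
        return True

    def add_inter_edge(self, a: NodeRef, b: NodeRef) -> bool:
        self.add_node(a.layer, a.id)
        self.add_node(b.layer, b.id)
        e = inter_edge(a, b)
        if e in self.inter_edges:
            return False
        self.inter_edges.add(e)
        return True

    # -- queries --------------------------------------------------------------

    def has_intra_edge(self, layer: str, u: str, v: str) -> bool:
        if u == v:
            return False
        return intra_edge(u, v) in self.intra_edges.get(layer, set())

    def has_inter_edge(self, a: NodeRef, b: NodeRef) -> bool:
        if a.layer == b.layer:
            return False
        return inter_edge(a, b) in self.inter_edges

    @property
    def n_nodes(self) -> int:
        return sum(len(s) for s in self.nodes.values())

    @property
    def n_intra_edges(self) -> int:
        return sum(len(s) for s in self.intra_edges.values())

    @property
    def n_edges(self) -> int:
        return self.n_intra_edges + len(self.inter_edges)

    def iter_edges(self) -> Iterator[tuple[NodeRef, NodeRef]]:
        """All edges as NodeRef pairs, intra first, in deterministic order."""
        for layer in self.layers:
            for u, v in sorted(self.intra_edges[layer]):
                yield NodeRef(layer, u), NodeRef(layer, v)
        for a, b in sorted(self.inter_edges):
            yield a, b

    def layer_graph(self, layer: str) -> nx.Graph:
        """The intra-layer graph of one layer as a networkx Graph."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes.get(layer, ()))
        g.add_edges_from(self.intra_edges.get(layer, ()))
        return g

    def copy(self, name: str | None = None) -> "MultilayerNetwork":
        return MultilayerNetwork(
            name=self.name if name is None else name,
            layers=list(self.layers),
            nodes={k: set(v) for k, v in self.nodes.items()},
            intra_edges={k: set(v) for k, v in self.intra_edges.items()},
            inter_edges=set(self.inter_edges),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        return (
            set(self.layers) == set(other.layers)
            and self.nodes == other.nodes
            and self.intra_edges == other.intra_edges
            and self.inter_edges == other.inter_edges
        )


def validate_network(net: MultilayerNetwork) -> list[str]:
    """Check every structural invariant; returns one message per violation.

    Reports rather than raises, so callers can surface all problems at once.
    """
    problems: list[str] = []
    if len(set(net.layers)) != len(net.layers):
        problems.append("duplicate layer identifiers in layer list")
    for layer in net.layers:
        if layer not in net.nodes:
            problems.append(f"layer {layer!r} has no node set")
    for layer, edges in net.intra_edges.items():
        declared = net.nodes.get(layer, set())
        for u, v in edges:
            if u == v:
                problems.append(f"self-loop ({layer}, {u})")
            for x in (u, v):
                if x not in declared:
                    problems.append(
                        f"intra-edge endpoint {x!r} not declared in layer {layer!r}"
                    )
    for a, b in net.inter_edges:
        if a.layer == b.layer:
            problems.append(f"inter-edge within a single layer: {a} -- {b}")
        for ref in (a, b):
            if ref.id not in net.nodes.get(ref.layer, set()):
                problems.append(f"inter-edge endpoint {ref} not declared")
    return problems


@dataclass(frozen=True, order=True)
class SeedEntry:
    """One candidate correspondence: same-layer node pair across the two inputs."""

    layer: str
    id1: str
    id2: str
    similarity: float


@dataclass
class SeedMap:
    """Similarity-scored same-layer node pairs linking network 1 to network 2."""

    entries: list[SeedEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SeedEntry]:
        return iter(self.entries)

    def by_layer(self) -> dict[str, list[SeedEntry]]:
        out: dict[str, list[SeedEntry]] = {}
        for e in self.entries:
            out.setdefault(e.layer, []).append(e)
        return out

    def validate(
        self, net1: MultilayerNetwork, net2: MultilayerNetwork
    ) -> None:
        """Raise ValidationError on the first entry inconsistent with the inputs."""
        for i, e in enumerate(self.entries):
            where = f"seed entry {i} ({e.layer}, {e.id1}, {e.id2})"
            if not 0.0 <= e.similarity <= 1.0:
                raise ValidationError(
                    f"{where}: similarity {e.similarity} outside [0, 1]"
                )
            if e.layer not in net1.nodes or e.layer not in net2.nodes:
                raise ValidationError(f"{where}: layer unknown to both networks")
            if e.id1 not in net1.nodes[e.layer]:
                raise ValidationError(
                    f"{where}: node {e.id1!r} absent from network 1 layer {e.layer!r}"
                )
            if e.id2 not in net2.nodes[e.layer]:
                raise ValidationError(
                    f"{where}: node {e.id2!r} absent from network 2 layer {e.layer!r}"
                )


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment-edge weights and the gap threshold Δ.

    Matches score highest; a mismatch (adjacency in only one network, the
    other pair far apart or disconnected) scores 0.5 and a gap (the other
    pair within Δ hops) 0.2.  Inter-layer analogues use 0.9 / 0.4.  All
    weights are user-tunable; the defaults are the published operating point.
    """

    w_match: float = 1.0
    w_mismatch: float = 0.5
    w_gap: float = 0.2
    w_het_match: float = 0.9
    w_het_mismatch: float = 0.4
    delta: int = 2

    def __post_init__(self) -> None:
        for name in ("w_match", "w_mismatch", "w_gap", "w_het_match", "w_het_mismatch"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.delta < 2:
            raise ParameterError("delta must be an integer >= 2")


def identity_seed_map(net: MultilayerNetwork) -> SeedMap:
    """Seed map pairing every node with itself at similarity 1.0 (self-alignment)."""
    entries = [
        SeedEntry(layer, v, v, 1.0)
        for layer in net.layers
        for v in sorted(net.nodes[layer])
    ]
    return SeedMap(entries)


def iter_node_refs(net: MultilayerNetwork) -> Iterable[NodeRef]:
    for layer in net.layers:
        for v in sorted(net.nodes[layer]):
            yield NodeRef(layer, v)
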