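"""Community mining on the alignment graph and conversion to local alignments.

The miner is pluggable: any algorithm that partitions a weighted undirected
graph can back it.  Two backends are registered — ``infomap`` (the default;
the two-level map-equation algorithm, via igraph) and ``louvain`` (weighted
modularity optimisation, via networkx).  Four further backend names from the
wider local-alignment literature are reserved in the registry but not
implemented here.

Because pair nodes are distinct per layer, the multilayer alignment graph
is a simple weighted graph over (layer, u, v) vertices and single-graph
community detection applies directly.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import igraph as ig
import networkx as nx

from .errors import ParameterError, ParseError, UsageError
from .align import AlignmentEdge, EdgeKind, MultilayerAlignmentGraph, PairNode

logger = logging.getLogger(__name__)

#: A backend maps (flattened weighted graph, seed) to a list of vertex sets.
Backend = Callable[[nx.Graph, int], list[set[PairNode]]]

DEFAULT_METHOD = "infomap"
RESERVED_BACKENDS = ("genlouvain", "abacus", "clique_percolation", "mdlp")


def _infomap_backend(g: nx.Graph, seed: int) -> list[set[PairNode]]:
    """Two-level map-equation communities (undirected, weighted), seeded."""
    nodes = sorted(g.nodes)
    index = {p: i for i, p in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g.edges[u, v]["weight"] for u, v in g.edges]
    graph = ig.Graph(n=len(nodes), edges=edges)
    ig.set_random_number_generator(random.Random(seed))
    try:
        clustering = graph.community_infomap(edge_weights=weights or None)
    finally:
        ig.set_random_number_generator(random)
    return [{nodes[i] for i in cluster} for cluster in clustering]


def _louvain_backend(g: nx.Graph, seed: int) -> list[set[PairNode]]:
    """Weighted Louvain modularity communities, seeded."""
    parts = nx.community.louvain_communities(g, weight="weight", seed=seed)
    return [set(c) for c in parts]


_REGISTRY: dict[str, Backend] = {
    "infomap": _infomap_backend,
    "louvain": _louvain_backend,
}


def register_backend(name: str, backend: Backend) -> None:
    _REGISTRY[name] = backend


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


@dataclass
class Community:
    """One mined community: a candidate local region of similarity."""

    id: int
    members: set[PairNode] = field(default_factory=set)
    internal_edges: set[AlignmentEdge] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


def detect_communities(
    graph: MultilayerAlignmentGraph,
    method: str = DEFAULT_METHOD,
    seed: int = 0,
) -> list[Community]:
    """Partition the alignment graph's pair nodes into communities.

    Every pair node lands in exactly one community (isolated pair nodes
    become singletons).  Deterministic given seed and backend.  Community
    ids are assigned in order of each community's smallest member.
    """
    if method in RESERVED_BACKENDS:
        raise UsageError(
            f"backend {method!r} is reserved but not implemented; "
            f"available: {', '.join(available_backends())}"
        )
    if method not in _REGISTRY:
        raise UsageError(
            f"unknown mining backend {method!r}; "
            f"available: {', '.join(available_backends())}"
        )
    flat = graph.to_networkx()
    if flat.number_of_nodes() == 0:
        return []
    raw = _REGISTRY[method](flat, seed)

    # sanity: backends must return a partition of the vertex set
    seen: set[PairNode] = set()
    for part in raw:
        if part & seen:
            raise ParameterError(f"backend {method!r} returned overlapping communities")
        seen |= part
    if seen != set(flat.nodes):
        raise ParameterError(f"backend {method!r} did not cover every pair node")

    raw.sort(key=lambda part: min(p.key for p in part))
    communities = []
    for cid, members in enumerate(raw, start=1):
        internal = {
            e for e in graph.edges if e.p in members and e.q in members
        }
        communities.append(Community(cid, set(members), internal))
    logger.info(
        "mined %d communities (sizes %s) with %s",
        len(communities),
        sorted((c.size for c in communities), reverse=True),
        method,
    )
    return communities


@dataclass
class AlignmentMapping:
    """The induced partial node mapping f: per-layer (u, v) pairs."""

    pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def layer_pairs(self, layer: str) -> set[tuple[str, str]]:
        return self.pairs.get(layer, set())

    @property
    def n_pairs(self) -> int:
        return sum(len(p) for p in self.pairs.values())

    def as_function(self, layer: str) -> dict[str, str]:
        return dict(self.layer_pairs(layer))


def communities_to_alignment(
    communities: list[Community], min_size: int = 2
) -> AlignmentMapping:
    """Project communities of at least *min_size* members to node pairs.

    The default drops singleton communities: a local region of similarity
    needs at least two matched pairs to carry any structure.
    """
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    mapping = AlignmentMapping()
    for c in communities:
        if c.size < min_size:
            continue
        for p in c.members:
            mapping.pairs.setdefault(p.layer, set()).add((p.u, p.v))
    return mapping


COMMUNITIES_HEADER = "#multiloal-communities v1"


def write_communities(
    communities: list[Community],
    graph: MultilayerAlignmentGraph,
    path: str | Path,
) -> None:
    """Write communities as member lines plus weighted, kind-labelled edges."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(COMMUNITIES_HEADER + "\n")
        for c in sorted(communities, key=lambda c: c.id):
            member_lines = sorted(
                f"C{c.id}\t{p.layer}\t{p.u}|{p.v}" for p in c.members
            )
            edge_lines = sorted(
                f"C{c.id}\t{e.p.layer}:{e.p.u}|{e.p.v}"
                f"\t{e.q.layer}:{e.q.u}|{e.q.v}\t{e.weight:g}\t{e.kind.value}"
                for e in c.internal_edges
            )
            for line in member_lines + edge_lines:
                fh.write(line + "\n")


def read_communities(path: str | Path) -> list[Community]:
    """Re-parse a communities file (similarities are not stored; default 1.0)."""
    path = Path(path)
    kind_by_value = {k.value: k for k in EdgeKind}
    by_id: dict[int, Community] = {}

    def parse_ref(token: str, lineno: int) -> PairNode:
        layer, _, pair = token.partition(":")
        u, sep, v = pair.partition("|")
        if not sep:
            raise ParseError(f"{path}:{lineno}: malformed pair token {token!r}")
        return PairNode(layer, u, v)

    with path.open(encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != COMMUNITIES_HEADER:
            raise ParseError(f"{path}: missing header {COMMUNITIES_HEADER!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if not cols[0].startswith("C"):
                raise ParseError(f"{path}:{lineno}: expected community id column")
            cid = int(cols[0][1:])
            comm = by_id.setdefault(cid, Community(cid))
            if len(cols) == 3:  # member line
                u, sep, v = cols[2].partition("|")
                if not sep:
                    raise ParseError(f"{path}:{lineno}: malformed member {cols[2]!r}")
                comm.members.add(PairNode(cols[1], u, v))
            elif len(cols) == 5:  # edge line
                p = parse_ref(cols[1], lineno)
                q = parse_ref(cols[2], lineno)
                kind = kind_by_value.get(cols[4])
                if kind is None:
                    raise ParseError(f"{path}:{lineno}: unknown edge kind {cols[4]!r}")
                comm.internal_edges.add(AlignmentEdge(p, q, kind, float(cols[3])))
            else:
                raise ParseError(f"{path}:{lineno}: unexpected column count {len(cols)}")
    return [by_id[cid] for cid in sorted(by_id)]
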