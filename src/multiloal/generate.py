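"""Synthetic multilayer benchmark networks and the edge-removal noise protocol.

The benchmark emulates the published evaluation setting: ten two-layer
networks of 30 nodes each (15 per layer) whose total edge counts are
{90, 96, 84, 78, 95, 88, 93, 83, 94, 96}, degraded by removing 5-25% of the
edges uniformly at random.  Within each layer edges are drawn as a uniform
G(n, m) random graph; inter-layer edges are drawn uniformly from the
bipartite pair set of each layer pair.  By default one fifth of the edges
are inter-layer, split evenly across layer pairs, so that inter-layer
conservation is measurable at every noise level.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError
from .model import MultilayerNetwork, NodeRef, SeedMap, identity_seed_map

#: Total edge counts of the ten benchmark networks N1..N10.
BENCHMARK_EDGE_COUNTS = (90, 96, 84, 78, 95, 88, 93, 83, 94, 96)
#: Edge-removal fractions used by the degradation protocol.
BENCHMARK_NOISE_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.25)


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Stable sub-stream seed < 2**31 from a master seed and string tokens."""
    key = "|".join([str(master_seed), *map(str, tokens)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class GeneratorParams:
    """Size parameters of one synthetic multilayer network."""

    n_nodes_total: int
    n_layers: int
    m_total: int
    inter_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ParameterError("need at least one layer")
        if self.n_nodes_total % self.n_layers != 0:
            raise ParameterError(
                f"{self.n_nodes_total} nodes cannot be split evenly over "
                f"{self.n_layers} layers"
            )
        if not 0.0 <= self.inter_fraction <= 1.0:
            raise ParameterError("inter_fraction must lie in [0, 1]")
        if self.m_total < 0:
            raise ParameterError("m_total must be non-negative")
        n_per = self.n_nodes_total // self.n_layers
        m_inter = round(self.inter_fraction * self.m_total)
        m_intra = self.m_total - m_inter
        n_pairs = self.n_layers * (self.n_layers - 1) // 2
        if self.n_layers == 1 and m_inter > 0:
            raise ParameterError("inter-layer edges require >= 2 layers")
        max_intra_per_layer = n_per * (n_per - 1) // 2
        max_inter_per_pair = n_per * n_per
        if m_intra > self.n_layers * max_intra_per_layer or (
            n_pairs and m_inter > n_pairs * max_inter_per_pair
        ):
            raise ParameterError(
                f"edge counts infeasible for {n_per} nodes per layer"
            )

    @property
    def n_per_layer(self) -> int:
        return self.n_nodes_total // self.n_layers


def _split_evenly(total: int, bins: int) -> list[int]:
    """Split *total* into *bins* near-equal parts, remainder to the first."""
    if bins == 0:
        return []
    base, rem = divmod(total, bins)
    return [base + (rem if i == 0 else 0) for i in range(bins)]


@dataclass(frozen=True)
class TrueMapping:
    """The known correct node correspondence, one-to-one within each layer."""

    pairs: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)

    def layer_pairs(self, layer: str) -> frozenset[tuple[str, str]]:
        return self.pairs.get(layer, frozenset())

    @property
    def n_pairs(self) -> int:
        return sum(len(p) for p in self.pairs.values())


def generate_multilayer(params: GeneratorParams, name: str = "synthetic") -> MultilayerNetwork:
    """Draw one random multilayer network with the exact edge counts requested.

    Per layer a uniform G(n, m) graph; per layer pair a uniform bipartite
    m-edge set.  Deterministic given ``params.seed``.
    """
    rng = random.Random(params.seed)
    n_per = params.n_per_layer
    layers = [f"L{i + 1}" for i in range(params.n_layers)]
    node_ids = [f"n{i + 1:02d}" for i in range(n_per)]

    net = MultilayerNetwork(name=name)
    for layer in layers:
        for v in node_ids:
            net.add_node(layer, v)

    m_inter = round(params.inter_fraction * params.m_total)
    m_intra = params.m_total - m_inter

    intra_quota = _split_evenly(m_intra, params.n_layers)
    all_pairs = list(itertools.combinations(node_ids, 2))
    for layer, quota in zip(layers, intra_quota):
        for u, v in rng.sample(all_pairs, quota):
            net.add_intra_edge(layer, u, v)

    layer_pairs = list(itertools.combinations(layers, 2))
    inter_quota = _split_evenly(m_inter, len(layer_pairs))
    bipartite = [(u, v) for u in node_ids for v in node_ids]
    for (la, lb), quota in zip(layer_pairs, inter_quota):
        for u, v in rng.sample(bipartite, quota):
            net.add_inter_edge(NodeRef(la, u), NodeRef(lb, v))
    return net


def degrade(net: MultilayerNetwork, noise: float, seed: int) -> MultilayerNetwork:
    """Remove ``floor(noise * |E|)`` edges uniformly at random.

    Edges are drawn from one pool spanning intra- and inter-layer edges;
    node sets are untouched, so isolates may appear.
    """
    if not 0.0 <= noise <= 1.0:
        raise ParameterError(f"noise level {noise} outside [0, 1]")
    tag = f"{net.name}.noise{int(round(noise * 100)):02d}" if net.name else ""
    out = net.copy(name=tag)
    pool = list(out.iter_edges())
    k = math.floor(noise * len(pool))
    rng = random.Random(seed)
    for a, b in rng.sample(pool, k):
        if a.layer == b.layer:
            out.intra_edges[a.layer].discard((a.id, b.id))
        else:
            out.inter_edges.discard((a, b))
    return out


def identity_true_mapping(net: MultilayerNetwork) -> TrueMapping:
    """True mapping (v, v) for every node; the benchmark's ground truth."""
    return TrueMapping(
        {
            layer: frozenset((v, v) for v in net.nodes[layer])
            for layer in net.layers
        }
    )


def identity_seeds(net: MultilayerNetwork) -> SeedMap:
    """Seed file content for self-alignment: (layer, v, v, 1.0) per node."""
    return identity_seed_map(net)


def benchmark_params(master_seed: int) -> list[tuple[str, GeneratorParams]]:
    """Parameters for the ten benchmark networks under one master seed."""
    return [
        (
            f"N{i + 1}",
            GeneratorParams(
                n_nodes_total=30,
                n_layers=2,
                m_total=m,
                inter_fraction=0.2,
                seed=derive_seed(master_seed, f"N{i + 1}"),
            ),
        )
        for i, m in enumerate(BENCHMARK_EDGE_COUNTS)
    ]


def generate_benchmark(master_seed: int) -> list[MultilayerNetwork]:
    """The ten benchmark networks, in order N1..N10."""
    return [generate_multilayer(p, name) for name, p in benchmark_params(master_seed)]


def make_benchmark_suite(out_dir: str | Path, seed: int) -> list[dict]:
    """Write the full benchmark to *out_dir*; returns the manifest rows.

    Emits each base network, its five degraded copies, an identity seed
    file per base network, and ``manifest.tsv``.
    """
    from .io import write_multilayer_edgelist, write_seed_map

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for name, params in benchmark_params(seed):
        net = generate_multilayer(params, name)
        base_file = out_dir / f"{name}.tsv"
        write_multilayer_edgelist(net, base_file)
        seeds_file = out_dir / f"{name}.seeds.tsv"
        write_seed_map(identity_seeds(net), seeds_file)
        manifest.append(
            {
                "name": name,
                "file": base_file.name,
                "layers": params.n_layers,
                "nodes": params.n_nodes_total,
                "edges": net.n_edges,
                "noise": 0.0,
                "seed": params.seed,
            }
        )
        for noise in BENCHMARK_NOISE_LEVELS:
            nseed = derive_seed(seed, name, noise)
            noisy = degrade(net, noise, nseed)
            pct = int(round(noise * 100))
            noisy_file = out_dir / f"{name}.noise{pct:02d}.tsv"
            write_multilayer_edgelist(noisy, noisy_file)
            manifest.append(
                {
                    "name": f"{name}.noise{pct:02d}",
                    "file": noisy_file.name,
                    "layers": params.n_layers,
                    "nodes": params.n_nodes_total,
                    "edges": noisy.n_edges,
                    "noise": noise,
                    "seed": nseed,
                }
            )
    cols = ["name", "file", "layers", "nodes", "edges", "noise", "seed"]
    with (out_dir / "manifest.tsv").open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in manifest:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return manifest
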