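"""Model-style front end: configure an aligner, fit it, inspect the results.

``MultilayerAligner`` holds the two input networks, the seed similarities
and the scoring configuration; ``fit`` runs graph construction and
community mining and returns an ``AlignmentResults`` carrying the
alignment graph, the communities, the induced node mapping, and evaluation
helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .align import (
    EdgeKind,
    MultilayerAlignmentGraph,
    build_multilayer_alignment_graph,
    write_alignment_graph,
)
from .errors import UsageError
from .metrics import EvaluationReport, evaluate_alignment
from .mining import (
    AlignmentMapping,
    Community,
    communities_to_alignment,
    detect_communities,
    write_communities,
    DEFAULT_METHOD,
)
from .model import MultilayerNetwork, ScoringConfig, SeedMap, identity_seed_map


@dataclass
class MultilayerAligner:
    """Local aligner of two multilayer networks guided by seed similarities."""

    net1: MultilayerNetwork
    net2: MultilayerNetwork
    seeds: SeedMap | None = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    method: str = DEFAULT_METHOD
    min_community_size: int = 2

    @classmethod
    def from_files(
        cls,
        net1_path: str | Path,
        net2_path: str | Path,
        seeds_path: str | Path | None = None,
        **kwargs,
    ) -> "MultilayerAligner":
        from .io import read_network, read_seed_map

        net1 = read_network(net1_path)
        net2 = read_network(net2_path)
        seeds = (
            read_seed_map(seeds_path, net1, net2) if seeds_path is not None else None
        )
        return cls(net1, net2, seeds, **kwargs)

    def _resolved_seeds(self) -> SeedMap:
        if self.seeds is not None:
            return self.seeds
        if self.net1.nodes == self.net2.nodes:
            # self-alignment convenience: identity seeds
            return identity_seed_map(self.net1)
        raise UsageError(
            "a seed-similarity map is required when the two networks differ"
        )

    def build_graph(self) -> MultilayerAlignmentGraph:
        return build_multilayer_alignment_graph(
            self.net1, self.net2, self._resolved_seeds(), self.scoring
        )

    def fit(self, seed: int = 0) -> "AlignmentResults":
        graph = self.build_graph()
        communities = detect_communities(graph, self.method, seed)
        mapping = communities_to_alignment(communities, self.min_community_size)
        return AlignmentResults(self, graph, communities, mapping, seed)


@dataclass
class AlignmentResults:
    """Fitted alignment: graph, communities, induced mapping, diagnostics."""

    model: MultilayerAligner
    graph: MultilayerAlignmentGraph
    communities: list[Community]
    mapping: AlignmentMapping
    seed: int

    def evaluate(self, truth) -> EvaluationReport:
        """Score the induced mapping against a known true mapping."""
        return evaluate_alignment(
            self.model.net1, self.model.net2, truth, self.mapping
        )

    def community_sizes(self) -> list[int]:
        return sorted((c.size for c in self.communities), reverse=True)

    def summary(self, truth=None) -> str:
        """Human-readable run summary; includes metrics when truth is given."""
        counts = self.graph.kind_counts()
        lines = [
            "Multilayer local alignment",
            "==========================",
            f"networks: {self.model.net1.name or 'net1'} vs "
            f"{self.model.net2.name or 'net2'}",
            f"layers aligned: {', '.join(self.graph.layers)}",
            f"mining backend: {self.model.method} (seed {self.seed})",
            f"pair nodes: {self.graph.n_pair_nodes}",
            "alignment edges:",
        ]
        for kind in EdgeKind:
            lines.append(f"  {kind.value:<24s} {counts[kind]}")
        lines.append(
            f"communities: {len(self.communities)} "
            f"(sizes {self.community_sizes()}, "
            f"min size kept {self.model.min_community_size})"
        )
        lines.append(f"mapped node pairs: {self.mapping.n_pairs}")
        if truth is not None:
            rep = self.evaluate(truth)
            lines.append("")
            lines.append(rep.to_frame().to_string(float_format="%.4f"))
        return "\n".join(lines)

    def save(self, out_dir: str | Path, prefix: str = "alignment") -> dict[str, Path]:
        """Write the alignment graph and communities files; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        graph_path = out_dir / f"{prefix}.graph.tsv"
        comm_path = out_dir / f"{prefix}.communities.tsv"
        write_alignment_graph(self.graph, graph_path)
        write_communities(self.communities, self.graph, comm_path)
        return {"graph": graph_path, "communities": comm_path}
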