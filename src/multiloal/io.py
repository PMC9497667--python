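"""Readers and writers for the package's TSV dialects.

Dialects (all UTF-8, tab-separated, ``#``-prefixed comment lines):

* edge list   — header ``#multiloal-edgelist v1``; one edge per line as
  ``layer_u  id_u  layer_v  id_v``; intra-layer iff the two layers match.
* seed map    — header ``#multiloal-seeds v1``; lines
  ``layer  id_in_net1  id_in_net2  similarity``.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .errors import ParseError, ValidationError
from .model import (
    MultilayerNetwork,
    NodeRef,
    SeedEntry,
    SeedMap,
    validate_network,
)

logger = logging.getLogger(__name__)

EDGELIST_HEADER = "#multiloal-edgelist v1"
SEEDS_HEADER = "#multiloal-seeds v1"


def _looks_like_directive(line: str) -> bool:
    """Directive comments are ``#word<TAB>...`` or ``#multiloal-...``."""
    head = line.split("\t", 1)[0]
    return "\t" in line and head[1:].isidentifier() or head.startswith("#multiloal-")


def _check_header(first_line: str | None, expected: str, path: Path) -> None:
    if first_line is None or first_line.strip() != expected:
        raise ParseError(
            f"{path}: first line must be the directive {expected!r}, "
            f"got {first_line!r}"
        )


def read_multilayer_edgelist(path: str | Path) -> MultilayerNetwork:
    """Parse a multilayer edge-list file into a validated network.

    Duplicate edge lines collapse to one edge with a warning; a fifth
    (weight) column, if present, is parsed and ignored with a warning since
    input graphs are treated as unweighted.
    """
    path = Path(path)
    net = MultilayerNetwork(name=path.stem)
    weight_warned = False
    with path.open(encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        _check_header(first, EDGELIST_HEADER, path)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#node\t"):
                    cols = line.split("\t")
                    if len(cols) != 3:
                        raise ParseError(
                            f"{path}:{lineno}: #node directive needs layer and id"
                        )
                    net.add_node(cols[1], cols[2])
                elif _looks_like_directive(line):
                    raise ParseError(f"{path}:{lineno}: unknown directive {line!r}")
                continue
            cols = line.split("\t")
            if len(cols) == 5:
                if not weight_warned:
                    logger.warning(
                        "%s:%d: weight column present; input edge weights are ignored",
                        path, lineno,
                    )
                    weight_warned = True
                cols = cols[:4]
            if len(cols) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(cols)}"
                )
            layer_u, id_u, layer_v, id_v = cols
            try:
                if layer_u == layer_v:
                    if id_u == id_v:
                        raise ValidationError(f"self-loop on node {id_u!r}")
                    fresh = net.add_intra_edge(layer_u, id_u, id_v)
                else:
                    fresh = net.add_inter_edge(
                        NodeRef(layer_u, id_u), NodeRef(layer_v, id_v)
                    )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if not fresh:
                logger.warning("%s:%d: duplicate edge line collapsed", path, lineno)
    problems = validate_network(net)
    if problems:  # defensive: construction should prevent this
        raise ValidationError(f"{path}: {'; '.join(problems)}")
    return net


def write_multilayer_edgelist(net: MultilayerNetwork, path: str | Path) -> None:
    """Write a network in the edge-list dialect, deterministically sorted."""
    path = Path(path)
    lines: list[str] = []
    for layer in sorted(net.layers):
        for u, v in sorted(net.intra_edges[layer]):
            lines.append(f"{layer}\t{u}\t{layer}\t{v}")
    for a, b in sorted(net.inter_edges):
        lines.append(f"{a.layer}\t{a.id}\t{b.layer}\t{b.id}")
    lines.sort()
    # isolated nodes survive round-trips through node directive comments
    isolated = [
        (layer, v)
        for layer in sorted(net.layers)
        for v in sorted(net.nodes[layer])
        if not any(v in e for e in net.intra_edges[layer])
        and not any(NodeRef(layer, v) in e for e in net.inter_edges)
    ]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(EDGELIST_HEADER + "\n")
        for layer, v in isolated:
            fh.write(f"#node\t{layer}\t{v}\n")
        for line in lines:
            fh.write(line + "\n")


#: Alias; isolated nodes ride along as ``#node`` directives.
read_network = read_multilayer_edgelist


def read_seed_map(
    path: str | Path,
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
) -> SeedMap:
    """Parse and validate a seed-similarity file against both input networks."""
    path = Path(path)
    entries: list[SeedEntry] = []
    with path.open(encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        _check_header(first, SEEDS_HEADER, path)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(cols)}"
                )
            layer, id1, id2, sim_str = cols
            try:
                sim = float(sim_str)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: similarity {sim_str!r} is not a number"
                ) from exc
            if not 0.0 <= sim <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: similarity {sim} outside [0, 1]"
                )
            entries.append(SeedEntry(layer, id1, id2, sim))
    seeds = SeedMap(entries)
    try:
        seeds.validate(net1, net2)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return seeds


def write_seed_map(seeds: SeedMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(SEEDS_HEADER + "\n")
        for e in sorted(seeds.entries):
            fh.write(f"{e.layer}\t{e.id1}\t{e.id2}\t{e.similarity:g}\n")
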