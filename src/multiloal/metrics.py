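"""Alignment-quality measures for multilayer local alignments.

Node correctness against a known true mapping M and produced mapping N:
``P-NC = |M∩N|/|M|``, ``R-NC = |M∩N|/|N|``, combined into F-NC (harmonic
mean by default).  Structural quality per layer is NCV-GS3: node coverage
NCV (fraction of all nodes of both networks entering the induced subgraphs
G1', G2') and edge conservation GS3 (conserved edges over the union of
induced edges), combined as their geometric mean.  Layer values average
into multilayer scores; inter-layer edges are pooled across all layer
pairs into a single inter-layer NCV-GS3.

Note the P-NC / R-NC orientation follows the source formulas, which swap
the usual precision/recall denominators; both are reported so either
convention can be read off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .mining import AlignmentMapping
from .model import MultilayerNetwork, NodeRef

Pairs = frozenset | set


def _combine_f(p: float, r: float, how: str) -> float:
    if how == "harmonic":
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)
    if how == "arithmetic":
        return (p + r) / 2
    raise ValueError(f"unknown F combination {how!r}")


def _combine_ncv_gs3(ncv: float, gs3: float, how: str) -> float:
    if how == "geometric":
        return math.sqrt(ncv * gs3)
    if how == "arithmetic":
        return (ncv + gs3) / 2
    raise ValueError(f"unknown NCV-GS3 combination {how!r}")


def node_correctness(
    M: Iterable[tuple[str, str]],
    N: Iterable[tuple[str, str]],
    f_combination: str = "harmonic",
) -> tuple[float, float, float]:
    """(P-NC, R-NC, F-NC) of mapping N against true mapping M."""
    M, N = set(M), set(N)
    if not M:
        raise UndefinedMetricError("node correctness undefined for an empty true mapping")
    inter = len(M & N)
    p_nc = inter / len(M)
    r_nc = inter / len(N) if N else 0.0
    return p_nc, r_nc, _combine_f(p_nc, r_nc, f_combination)


def _mean(values: list[float], what: str) -> float:
    if not values:
        raise UndefinedMetricError(f"{what} undefined with no layers")
    return sum(values) / len(values)


def multilayer_f_nc(per_layer_f_nc: list[float]) -> float:
    """Arithmetic mean of per-layer F-NC values."""
    return _mean(per_layer_f_nc, "multilayer F-NC")


def multilayer_ncv_gs3(per_layer_ncv_gs3: list[float]) -> float:
    """Arithmetic mean of per-layer NCV-GS3 values."""
    return _mean(per_layer_ncv_gs3, "multilayer NCV-GS3")


def _check_one_to_one(pairs: set[tuple[str, str]], where: str) -> None:
    us = {u for u, _ in pairs}
    vs = {v for _, v in pairs}
    if len(us) != len(pairs) or len(vs) != len(pairs):
        raise ValidationError(f"alignment mapping not one-to-one in {where}")


def ncv_gs3_layer(
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
    layer: str,
    f_pairs: set[tuple[str, str]],
    combination: str = "geometric",
) -> tuple[float, float, float]:
    """(NCV, GS3, NCV-GS3) for one layer's intra-layer edges.

    G1' and G2' are the subgraphs induced by the domain and image of the
    layer mapping.  GS3 is 1 when neither induced subgraph has edges.
    """
    _check_one_to_one(f_pairs, f"layer {layer!r}")
    f = dict(f_pairs)
    dom = set(f)
    img = set(f.values())

    n_total = len(net1.nodes.get(layer, ())) + len(net2.nodes.get(layer, ()))
    ncv = (len(dom) + len(img)) / n_total if n_total else 0.0

    e1 = {e for e in net1.intra_edges.get(layer, set()) if e[0] in dom and e[1] in dom}
    e2 = {e for e in net2.intra_edges.get(layer, set()) if e[0] in img and e[1] in img}
    conserved = sum(
        1
        for a, b in e1
        if tuple(sorted((f[a], f[b]))) in e2
    )
    denom = len(e1) + len(e2) - conserved
    gs3 = 1.0 if denom == 0 else conserved / denom
    return ncv, gs3, _combine_ncv_gs3(ncv, gs3, combination)


def interlayer_ncv_gs3(
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
    mapping: AlignmentMapping,
    combination: str = "geometric",
) -> float:
    """NCV-GS3 over all inter-layer edges pooled across layer pairs.

    Coverage counts each aligned node once over the union of all layers;
    conservation compares the inter-layer edges induced among aligned nodes
    in network 1 with their images in network 2.
    """
    f: dict[NodeRef, NodeRef] = {}
    for layer, pairs in mapping.pairs.items():
        _check_one_to_one(pairs, f"layer {layer!r}")
        for u, v in pairs:
            f[NodeRef(layer, u)] = NodeRef(layer, v)
    dom = set(f)
    img = set(f.values())

    n_total = net1.n_nodes + net2.n_nodes
    ncv = (len(dom) + len(img)) / n_total if n_total else 0.0

    e1 = {e for e in net1.inter_edges if e[0] in dom and e[1] in dom}
    e2 = {e for e in net2.inter_edges if e[0] in img and e[1] in img}
    conserved = 0
    for a, b in e1:
        fa, fb = f[a], f[b]
        if (min(fa, fb), max(fa, fb)) in e2:
            conserved += 1
    denom = len(e1) + len(e2) - conserved
    gs3 = 1.0 if denom == 0 else conserved / denom
    return _combine_ncv_gs3(ncv, gs3, combination)


def _truth_pairs(truth, layer: str) -> set[tuple[str, str]]:
    """Accept a TrueMapping-like object or a plain layer -> pairs mapping."""
    if hasattr(truth, "layer_pairs"):
        return set(truth.layer_pairs(layer))
    if isinstance(truth, Mapping):
        return set(truth.get(layer, ()))
    raise TypeError(f"unsupported true-mapping object {type(truth)!r}")


def _incident_to_inter(net: MultilayerNetwork) -> set[NodeRef]:
    out: set[NodeRef] = set()
    for a, b in net.inter_edges:
        out.add(a)
        out.add(b)
    return out


@dataclass
class EvaluationReport:
    """Per-layer, multilayer, and inter-layer quality of one alignment."""

    per_layer: dict[str, dict[str, float]] = field(default_factory=dict)
    multilayer_f_nc: float = 0.0
    multilayer_ncv_gs3: float = 0.0
    interlayer_ncv_gs3: float = 0.0
    interlayer_f_nc: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for layer in sorted(self.per_layer):
            rows.append({"scope": layer, **self.per_layer[layer]})
        rows.append(
            {
                "scope": "multilayer",
                "f_nc": self.multilayer_f_nc,
                "ncv_gs3": self.multilayer_ncv_gs3,
            }
        )
        rows.append(
            {
                "scope": "interlayer",
                "f_nc": self.interlayer_f_nc,
                "ncv_gs3": self.interlayer_ncv_gs3,
            }
        )
        return pd.DataFrame(rows).set_index("scope")

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def evaluate_alignment(
    net1: MultilayerNetwork,
    net2: MultilayerNetwork,
    truth,
    mapping: AlignmentMapping,
    f_combination: str = "harmonic",
    ncv_gs3_combination: str = "geometric",
) -> EvaluationReport:
    """Fill a full EvaluationReport for one alignment run.

    *truth* is the known correct mapping (per-layer pairs); *mapping* is
    the mapping induced by the mined communities.  Inter-layer F-NC pools
    node pairs whose members touch an inter-layer edge in either input
    (all pairs, when neither network has inter-layer edges).
    """
    report = EvaluationReport()
    f_vals: list[float] = []
    e_vals: list[float] = []
    for layer in net1.layers:
        if layer not in net2.nodes:
            continue
        M = _truth_pairs(truth, layer)
        N = mapping.layer_pairs(layer)
        p, r, fnc = node_correctness(M, N, f_combination)
        ncv, gs3, ncvgs3 = ncv_gs3_layer(
            net1, net2, layer, N, ncv_gs3_combination
        )
        report.per_layer[layer] = {
            "p_nc": p,
            "r_nc": r,
            "f_nc": fnc,
            "ncv": ncv,
            "gs3": gs3,
            "ncv_gs3": ncvgs3,
        }
        f_vals.append(fnc)
        e_vals.append(ncvgs3)
    report.multilayer_f_nc = multilayer_f_nc(f_vals)
    report.multilayer_ncv_gs3 = multilayer_ncv_gs3(e_vals)
    report.interlayer_ncv_gs3 = interlayer_ncv_gs3(
        net1, net2, mapping, ncv_gs3_combination
    )

    touch1 = _incident_to_inter(net1)
    touch2 = _incident_to_inter(net2)
    restrict = bool(touch1 or touch2)

    def pooled(pairs_by_layer) -> set[tuple[str, str, str]]:
        out = set()
        for layer in report.per_layer:
            for u, v in pairs_by_layer(layer):
                if not restrict or NodeRef(layer, u) in touch1 or NodeRef(layer, v) in touch2:
                    out.add((layer, u, v))
        return out

    M_inter = pooled(lambda layer: _truth_pairs(truth, layer))
    N_inter = pooled(mapping.layer_pairs)
    if M_inter:
        _, _, report.interlayer_f_nc = node_correctness(
            M_inter, N_inter, f_combination
        )
    else:
        report.interlayer_f_nc = report.multilayer_f_nc
    return report
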