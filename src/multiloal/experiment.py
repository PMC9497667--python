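"""The benchmark robustness experiment: self-alignment under edge-removal noise.

Each benchmark network is aligned against itself (noise 0) and against
degraded copies with 5-25% of edges removed, using identity seeds and the
identity mapping as ground truth.  With the default ten networks and six
noise levels this records 60 alignment runs per mining method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .aligner import MultilayerAligner
from .errors import MultiloalError, ParameterError
from .generate import (
    BENCHMARK_EDGE_COUNTS,
    BENCHMARK_NOISE_LEVELS,
    GeneratorParams,
    degrade,
    derive_seed,
    generate_multilayer,
    identity_seeds,
    identity_true_mapping,
)
from .model import ScoringConfig

logger = logging.getLogger(__name__)

#: Columns of the long-form per-run results table.
RUN_COLUMNS = [
    "network", "noise", "method", "n_communities", "n_mapped_pairs",
    "intra_ncv_gs3", "intra_f_nc", "inter_ncv_gs3", "inter_f_nc", "error",
]


@dataclass
class ExperimentConfig:
    """Parameters of one experiment sweep."""

    edge_counts: tuple[int, ...] = BENCHMARK_EDGE_COUNTS
    n_nodes_total: int = 30
    n_layers: int = 2
    inter_fraction: float = 0.2
    noise_levels: tuple[float, ...] = (0.0, *BENCHMARK_NOISE_LEVELS)
    methods: tuple[str, ...] = ("infomap",)
    master_seed: int = 0
    min_community_size: int = 2
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.noise_levels):
            raise ParameterError("noise levels must lie in [0, 1]")

    def network_names(self) -> list[str]:
        return [f"N{i + 1}" for i in range(len(self.edge_counts))]


def run_experiment(
    cfg: ExperimentConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full sweep; returns (per-run long table, per-network mean/sd).

    A failing run is logged, marked in the ``error`` column and skipped in
    the summary; the sweep continues.
    """
    cfg = cfg or ExperimentConfig()
    rows: list[dict] = []
    for name, m_total in zip(cfg.network_names(), cfg.edge_counts):
        params = GeneratorParams(
            n_nodes_total=cfg.n_nodes_total,
            n_layers=cfg.n_layers,
            m_total=m_total,
            inter_fraction=cfg.inter_fraction,
            seed=derive_seed(cfg.master_seed, name),
        )
        base = generate_multilayer(params, name)
        truth = identity_true_mapping(base)
        seeds = identity_seeds(base)
        for noise in cfg.noise_levels:
            noisy = (
                base
                if noise == 0
                else degrade(base, noise, derive_seed(cfg.master_seed, name, noise))
            )
            for method in cfg.methods:
                row = {
                    "network": name,
                    "noise": noise,
                    "method": method,
                    "error": "",
                }
                try:
                    aligner = MultilayerAligner(
                        base,
                        noisy,
                        seeds,
                        scoring=cfg.scoring,
                        method=method,
                        min_community_size=cfg.min_community_size,
                    )
                    res = aligner.fit(
                        seed=derive_seed(cfg.master_seed, name, noise, method, "mine")
                    )
                    rep = res.evaluate(truth)
                    row.update(
                        n_communities=len(res.communities),
                        n_mapped_pairs=res.mapping.n_pairs,
                        intra_ncv_gs3=rep.multilayer_ncv_gs3,
                        intra_f_nc=rep.multilayer_f_nc,
                        inter_ncv_gs3=rep.interlayer_ncv_gs3,
                        inter_f_nc=rep.interlayer_f_nc,
                    )
                except MultiloalError as exc:
                    logger.error("run %s noise=%s %s failed: %s", name, noise, method, exc)
                    row["error"] = str(exc)
                rows.append(row)
    runs = pd.DataFrame(rows, columns=RUN_COLUMNS)
    summary = summarise(runs)
    return runs, summary


METRIC_COLUMNS = ["intra_ncv_gs3", "intra_f_nc", "inter_ncv_gs3", "inter_f_nc"]


def summarise(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of every metric per (network, method), across noise levels."""
    ok = runs[runs["error"] == ""]
    g = ok.groupby(["network", "method"], sort=False)[METRIC_COLUMNS]
    out = g.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def wide_table(runs: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot one metric into a (network, noise) x method table for reading."""
    return runs.pivot_table(
        index=["network", "noise"], columns="method", values=metric, sort=False
    )


def write_results(
    runs: pd.DataFrame, summary: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runs_path = out_dir / "runs.tsv"
    summary_path = out_dir / "summary.tsv"
    runs.to_csv(runs_path, sep="\t", index=False, float_format="%.6g")
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6g")
    return {"runs": runs_path, "summary": summary_path}
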