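"""End-to-end run orchestration: config in, artifact directory out.

``run_pipeline`` executes load -> log1p -> [pseudotime binning] ->
couplings -> velocities -> {corr | granger | both} -> edge lists ->
[evaluation] and writes every intermediate product (couplings, velocity
fields, per-interval and global weight matrices, ranked edges, metrics,
logs) beside a resolved copy of the configuration, so a run can be
reproduced bit-exactly from its own output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corr as _corr
from .coupling import CouplingParams, fit_all_couplings, write_coupling
from .dataset import (
    TimeSeriesDataset,
    bin_pseudotime,
    load_dataset,
    log1p_transform,
    normalize_total_counts,
    read_dataset_dir,
    split_branches,
)
from .evaluation import GroundTruth, evaluate_network
from .granger import GrangerParams, add_stimulus_gene, granger_network
from .networks import WeightMatrix, aggregate_branches, threshold_edges, write_edge_list
from .velocity import compute_velocities

logger = logging.getLogger("velogrn")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (YAML/JSON serialisable)."""

    dataset_dir: str
    output_dir: str
    method: str = "both"  # corr | granger | both
    alpha: float = 0.5
    epsilon: float = 0.01
    knn_cap: int = 50
    knn_frac: float = 0.2
    feature_metric: str = "euclidean"
    gw_loss: str = "square"
    max_iter: int = 1000
    tol: float = 1e-9
    lam: float = 1.0
    l1_ratio: float = 0.5
    lag: int = 1
    stimulus_time: float | None = None
    normalize_totals: bool = False
    pseudotime_bins: int | None = None
    branch_mode: str = "combined"  # combined | split
    branch_aggregate: str = "sum"  # sum | maxabs
    windows: list[list[float]] = field(default_factory=list)
    edge_threshold: float | None = None
    edge_top_fraction: float | None = None
    ground_truth: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _coupling_params(cfg: RunConfig) -> CouplingParams:
    return CouplingParams(
        alpha=cfg.alpha, epsilon=cfg.epsilon, knn_cap=cfg.knn_cap,
        knn_frac=cfg.knn_frac, feature_metric=cfg.feature_metric,
        gw_loss=cfg.gw_loss, max_iter=cfg.max_iter, tol=cfg.tol,
    )


def _write_matrix(M: np.ndarray, genes: list[str], path: Path) -> None:
    pd.DataFrame(M, index=genes, columns=genes).to_csv(path, sep="\t")


def _infer_one(
    ds: TimeSeriesDataset, cfg: RunConfig, outdir: Path
) -> dict[str, WeightMatrix]:
    """Couple, differentiate, infer; write artifacts under outdir."""
    params = _coupling_params(cfg)
    couplings = fit_all_couplings(ds, params)
    cdir = outdir / "couplings"
    cdir.mkdir(parents=True, exist_ok=True)
    for k, c in enumerate(couplings):
        write_coupling(c, cdir / f"coupling_{k}.tsv", params)
        logger.info(
            "interval %d (%g -> %g): objective=%.6g converged=%s",
            k, c.source_time, c.target_time, c.objective, c.converged,
        )

    V = compute_velocities(ds, couplings)
    if cfg.stimulus_time is not None:
        V = add_stimulus_gene(V, cfg.stimulus_time)
    V = _corr.normalize_velocity_std(V)
    vdir = outdir / "velocities"
    vdir.mkdir(exist_ok=True)
    for k, Vk in enumerate(V.velocities):
        pd.DataFrame(Vk, index=V.gene_names).to_csv(
            vdir / f"velocity_t{k}.tsv", sep="\t"
        )

    methods: dict[str, WeightMatrix] = {}
    if cfg.method in ("corr", "both"):
        methods["corr"] = _corr.time_lagged_correlation(V, couplings, lag=cfg.lag)
    if cfg.method in ("granger", "both"):
        methods["granger"] = granger_network(
            V, couplings, GrangerParams(lam=cfg.lam, l1_ratio=cfg.l1_ratio)
        )

    for name, W in methods.items():
        _write_matrix(W.matrix, W.genes, outdir / f"weights_{name}.tsv")
        for k, A in enumerate(W.per_interval or []):
            _write_matrix(A, W.genes, outdir / f"weights_{name}_interval{k}.tsv")
        edges = threshold_edges(
            W, threshold=cfg.edge_threshold, top_fraction=cfg.edge_top_fraction
        )
        write_edge_list(edges, outdir / f"edges_{name}.tsv")
        from .networks import window_grn

        for lo, hi in cfg.windows:
            Ww = window_grn(W, lo, hi)
            _write_matrix(
                Ww.matrix, Ww.genes, outdir / f"weights_{name}_window_{lo}_{hi}.tsv"
            )
    return methods


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full workflow described by ``cfg``.

    Returns the output directory.  On failure, partial outputs are kept
    and a FAILED marker naming the stage and cause is written.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_file(out / "config.resolved.yaml")
    logging.basicConfig(level=logging.INFO)
    stage = "load"
    try:
        ds = read_dataset_dir(cfg.dataset_dir)
        stage = "preprocess"
        if cfg.normalize_totals:
            ds = normalize_total_counts(ds)
        if not ds.transformed:
            ds = log1p_transform(ds)
        if cfg.pseudotime_bins is not None:
            ds = bin_pseudotime(ds, cfg.pseudotime_bins)

        stage = "inference"
        if cfg.branch_mode == "split":
            branches = split_branches(ds)
            per_branch: dict[str, list[WeightMatrix]] = {}
            for lab, sub in branches.items():
                sub_out = out / f"branch_{lab}"
                sub_out.mkdir(exist_ok=True)
                for name, W in _infer_one(sub, cfg, sub_out).items():
                    per_branch.setdefault(name, []).append(W)
            methods = {
                name: aggregate_branches(ws, mode=cfg.branch_aggregate)
                for name, ws in per_branch.items()
            }
            for name, W in methods.items():
                _write_matrix(W.matrix, W.genes, out / f"weights_{name}.tsv")
                write_edge_list(
                    threshold_edges(
                        W,
                        threshold=cfg.edge_threshold,
                        top_fraction=cfg.edge_top_fraction,
                    ),
                    out / f"edges_{name}.tsv",
                )
        else:
            methods = _infer_one(ds, cfg, out)

        stage = "evaluation"
        if cfg.ground_truth is not None:
            gt = GroundTruth.from_edge_list(
                cfg.ground_truth,
                genes=[
                    g
                    for g, s in zip(
                        methods[next(iter(methods))].genes,
                        methods[next(iter(methods))].stimulus_flags
                        if methods[next(iter(methods))].stimulus_flags is not None
                        else [False] * len(methods[next(iter(methods))].genes),
                    )
                    if not s
                ],
            )
            metrics = {name: evaluate_network(W, gt) for name, W in methods.items()}
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise
    return out
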