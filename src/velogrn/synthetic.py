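"""Seeded simulation of stimulus-driven time-stamped single-cell data.

The generator emulates the benchmark regime for time-series GRN
inference: a known signed network of m genes, a stimulus switched on at
the start of the experiment, about ten observation times, and a fresh
cohort of cells sampled destructively at each time (no cell is observed
twice).

Each cell carries an independent latent trajectory s(t) of log-scale
expression around a baseline b, integrated by Euler-Maruyama:

    ds = (A^T act(s - b) - gamma (s - b) + u(t)) dt + sigma dW,

where A is the signed adjacency (A[g1, g2] = weight of g1 -> g2), act is
the identity (``linear_sde``) or a saturating tanh (``hill_activation``),
gamma is first-order decay, and u(t) applies the stimulus drive to one
gene from the onset time onward.  Observed counts are round(exp(s) - 1),
so the conventional log1p preprocessing recovers the latent scale up to
rounding.  Technical dropout is modelled as independent zeroing of
counts at a fixed rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .dataset import TimeSeriesDataset
from .evaluation import GroundTruth

__all__ = ["SimConfig", "default_network", "simulate_dataset", "inject_dropout"]


def default_network() -> tuple[list[str], np.ndarray]:
    """A 5-gene cascade with 4 signed edges (3 activations, 1 inhibition).

    g0 -> g1 (+), g1 -> g2 (+), g1 -> g3 (-), g2 -> g4 (+); the stimulus
    drives g0.  Small, acyclic and signed - the canonical smoke-test
    topology for stimulus-response network inference.
    """
    genes = [f"g{i}" for i in range(5)]
    A = np.zeros((5, 5))
    A[0, 1] = 1.0
    A[1, 2] = 1.0
    A[1, 3] = -1.0
    A[2, 4] = 1.0
    return genes, A


@dataclass
class SimConfig:
    """Simulation setting.

    Defaults mirror the benchmark regime: 10 time points with 200 cells
    drawn at each.  ``adjacency`` holds signed edge weights (sign = the
    ground truth; magnitude = regulation strength); ``interaction_scale``
    multiplies it inside the drift.  Times are t_k = k * dt.
    """

    adjacency: np.ndarray | None = None
    gene_names: list[str] | None = None
    n_timepoints: int = 10
    cells_per_time: int = 200
    dt: float = 1.0
    noise_sd: float = 0.15
    decay: float = 1.0
    interaction_scale: float = 1.2
    baseline: float = 1.5
    init_sd: float = 0.1
    stimulus_gene: int = 0
    stimulus_time: float = 0.0
    stimulus_amplitude: float = 1.5
    dynamics: Literal["linear_sde", "hill_activation"] = "linear_sde"
    dropout_rate: float = 0.0
    n_substeps: int = 20
    divergence_bound: float = 50.0
    seed: int = 0

    def resolve(self) -> tuple[list[str], np.ndarray]:
        if self.adjacency is None:
            return default_network()
        A = np.asarray(self.adjacency, dtype=float)
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        genes = self.gene_names or [f"g{i}" for i in range(A.shape[0])]
        return genes, A


def simulate_dataset(cfg: SimConfig) -> tuple[TimeSeriesDataset, GroundTruth | None]:
    """Simulate a time-stamped dataset and its signed ground truth.

    One independent latent trajectory per (cell, observation time) pair is
    integrated from t = 0; the cohort observed at t_k reports counts at
    that time only (destructive sampling).  Deterministic for a fixed
    seed; the seed fans out to per-stage substreams so adding a stage
    never perturbs earlier draws.
    """
    genes, A = cfg.resolve()
    m = len(genes)
    N, cpt = cfg.n_timepoints, cfg.cells_per_time
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_noise, _rng_dropout = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    n_traj = N * cpt
    s = cfg.baseline + cfg.init_sd * rng_init.normal(size=(n_traj, m))
    times = np.arange(N) * cfg.dt
    h = cfg.dt / cfg.n_substeps
    W = cfg.interaction_scale * A  # drift couplings, signed

    observed = np.empty((N, cpt, m))
    observed[0] = s[:cpt]  # cohort 0 observed at t = 0
    t = 0.0
    for k in range(1, N):
        for _ in range(cfg.n_substeps):
            dev = s - cfg.baseline
            act = np.tanh(dev) if cfg.dynamics == "hill_activation" else dev
            u = np.zeros(m)
            if t >= cfg.stimulus_time:
                u[cfg.stimulus_gene] = cfg.stimulus_amplitude
            drift = act @ W - cfg.decay * dev + u
            s = s + h * drift + np.sqrt(h) * cfg.noise_sd * rng_noise.normal(
                size=s.shape
            )
            t += h
        if np.abs(s - cfg.baseline).max() > cfg.divergence_bound:
            raise ValueError(
                "dynamics diverged; lower the spectral radius of the "
                "adjacency or increase decay"
            )
        observed[k] = s[k * cpt : (k + 1) * cpt]

    counts = np.round(np.expm1(np.clip(observed, 0.0, None)))
    expression = [counts[k].T for k in range(N)]  # genes x cells
    cell_ids = [[f"t{k}_c{j}" for j in range(cpt)] for k in range(N)]
    ds = TimeSeriesDataset(
        gene_names=genes,
        time_points=times,
        expression=expression,
        cell_ids=cell_ids,
    )
    # an edgeless adjacency (null model) has no meaningful ground truth
    gt = (
        GroundTruth(genes=genes, adjacency=np.sign(A).astype(int))
        if np.any(A != 0)
        else None
    )
    if cfg.dropout_rate > 0:
        ds = inject_dropout(ds, cfg.dropout_rate, rng=_rng_dropout)
    return ds, gt


def inject_dropout(
    ds: TimeSeriesDataset,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeriesDataset:
    """Zero each count independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if rate == 0:
        return ds
    if rng is None:
        rng = np.random.default_rng(seed)
    out = [X * (rng.random(X.shape) >= rate) for X in ds.expression]
    return replace(ds, expression=out)
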