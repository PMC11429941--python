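"""Self-contained recovery benchmark on simulated data.

Runs the full pipeline - simulation from the default 5-gene signed
cascade, log1p, fused GW couplings, velocities, stimulus gene, and both
inference methods - and scores the result against the simulation's
ground truth.  Used by the acceptance script and the end-to-end tests;
also a convenient template for benchmarking on other configurations.
"""

from __future__ import annotations

import numpy as np

from .corr import normalize_velocity_std, time_lagged_correlation
from .coupling import CouplingParams, fit_all_couplings
from .dataset import log1p_transform
from .evaluation import evaluate_network
from .granger import GrangerParams, add_stimulus_gene, granger_network
from .synthetic import SimConfig, simulate_dataset
from .velocity import compute_velocities

__all__ = ["run_recovery_benchmark", "mean_metrics"]


def run_recovery_benchmark(
    seed: int,
    dropout_rate: float = 0.0,
    sim_config: SimConfig | None = None,
    coupling_params: CouplingParams | None = None,
    granger_params: GrangerParams | None = None,
) -> dict[str, dict[str, float]]:
    """One full pipeline run on one simulated dataset; metrics per method.

    The couplings are solved once and shared by both inference methods.
    Returns ``{"corr": {...}, "granger": {...}}`` with the metric record
    of :func:`velogrn.evaluation.evaluate_network`.
    """
    cfg = sim_config or SimConfig()
    cfg = SimConfig(**{**cfg.__dict__, "seed": seed, "dropout_rate": dropout_rate})
    ds, gt = simulate_dataset(cfg)
    if gt is None:
        raise ValueError("benchmark needs a network with at least one edge")
    ds = log1p_transform(ds)
    couplings = fit_all_couplings(ds, coupling_params or CouplingParams())
    V = compute_velocities(ds, couplings)
    V = add_stimulus_gene(V, float(cfg.stimulus_time))
    V = normalize_velocity_std(V)
    W_corr = time_lagged_correlation(V, couplings)
    W_granger = granger_network(V, couplings, granger_params or GrangerParams())
    return {
        "corr": evaluate_network(W_corr, gt),
        "granger": evaluate_network(W_granger, gt),
    }


def mean_metrics(results: list[dict[str, dict[str, float]]]) -> dict[str, dict[str, float]]:
    """Average metric records over replicate runs."""
    out: dict[str, dict[str, float]] = {}
    for method in results[0]:
        keys = results[0][method].keys()
        out[method] = {
            k: float(np.mean([r[method][k] for r in results])) for k in keys
        }
    return out
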