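"""OT-weighted time-lagged correlation of gene velocities.

For genes g1, g2 the lag-``lag`` correlation is

    C_{g1,g2} = 1/(N-lag) * sum_k sum_{c,c~}
                  v_{g1}(x^{t_k,c}) v_{g2}(x^{t_{k+lag}, c~}) T^{t_k,t_{k+lag}}_{c,c~},

the product of earlier and later velocities weighted by the transport
plan (composed across ``lag`` consecutive plans when lag > 1).  With one
cell per time point and T = 1 this reduces to the canonical lagged
product of a single trajectory.  Velocities are first normalised to unit
pooled standard deviation per gene, making C unit-free; means are *not*
subtracted, since the sign of a velocity is biologically meaningful.

C_{g1,g2} >> 0 suggests activation of g2 by g1 (g1 changes first, in the
same direction); C_{g1,g2} < 0 suggests inhibition.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .coupling import CouplingSet, compose_lagged
from .networks import WeightMatrix
from .velocity import VelocityField

__all__ = [
    "normalize_velocity_std",
    "time_lagged_correlation",
    "in_out_degree",
]


def normalize_velocity_std(V: VelocityField) -> VelocityField:
    """Scale each gene's velocities to unit standard deviation.

    The standard deviation is pooled over all cells at all time points.
    Zero-variance genes are left untouched (their velocities stay zero);
    stimulus genes keep their raw 0/1 velocities.  Means are not
    subtracted.  Idempotent.
    """
    pooled = V.pooled()
    sd = pooled.std(axis=1)
    scale = np.ones_like(sd)
    ok = (sd > 0) & ~V.stimulus_flags
    scale[ok] = 1.0 / sd[ok]
    return replace(
        V,
        velocities=[Vk * scale[:, None] for Vk in V.velocities],
        normalized=True,
    )


def time_lagged_correlation(
    V: VelocityField, couplings: CouplingSet, lag: int = 1
) -> WeightMatrix:
    """OT-weighted lagged correlation matrix between all gene pairs.

    Stimulus genes may act only as sources: their columns are zeroed.
    The per-interval summands (without the 1/(N-lag) prefactor) are
    retained for dynamic, per-window networks.
    """
    N = V.n_timepoints
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= N:
        raise ValueError(f"lag ({lag}) must be smaller than N ({N})")
    if not V.normalized:
        V = normalize_velocity_std(V)
    per_interval: list[np.ndarray] = []
    intervals: list[tuple[float, float]] = []
    for k in range(N - lag):
        plan = compose_lagged(couplings, k, lag).T  # the coupling matrix
        Ck = V.velocities[k] @ plan @ V.velocities[k + lag].T
        if V.stimulus_flags.any():
            Ck[:, V.stimulus_flags] = 0.0
        per_interval.append(Ck)
        intervals.append((float(V.time_points[k]), float(V.time_points[k + lag])))
    C = np.sum(per_interval, axis=0) / (N - lag)
    return WeightMatrix(
        genes=list(V.gene_names),
        matrix=C,
        method="corr",
        lag=lag,
        per_interval=per_interval,
        intervals=intervals,
        stimulus_flags=V.stimulus_flags.copy(),
    )


def in_out_degree(
    W: WeightMatrix,
    signed: bool = False,
    threshold: float | None = None,
    threshold_abs: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """In/out weight ratio per gene: deg(g) = sum_{g~!=g} |C_{g~,g}| /
    sum_{g~!=g} |C_{g,g~}|.

    deg < 1 marks regulator-like (upstream, TF-like) genes; deg > 1 marks
    target-like (downstream) genes.  By default absolute weights are used;
    ``signed=True`` sums raw weights instead.  An optional ``threshold``
    zeroes small entries first (on |C| when ``threshold_abs``, else on raw
    values).  Returns (deg, undefined_flag); genes with zero outgoing
    weight get deg = +inf and a raised flag.
    """
    C = W.matrix.copy()
    np.fill_diagonal(C, 0.0)
    if threshold is not None:
        basis = np.abs(C) if threshold_abs else C
        C[basis < threshold] = 0.0
    vals = C if signed else np.abs(C)
    incoming = vals.sum(axis=0)
    outgoing = vals.sum(axis=1)
    undefined = outgoing == 0
    deg = np.full(W.n_genes, np.inf)
    deg[~undefined] = incoming[~undefined] / outgoing[~undefined]
    return deg, undefined
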