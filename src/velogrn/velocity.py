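"""Gene velocities from optimal-transport couplings.

Past/future cell states are predicted by barycentric projection of the
transport plan; the per-gene, per-cell velocity is the finite difference
of the predicted states, in expression units per time unit.  Forward
differences are used at the first time point, backward at the last, and a
gap-weighted centered scheme at interior points.  Velocities are computed
on log-transformed expression, the same representation the transport
costs use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .coupling import Coupling, CouplingSet
from .dataset import TimeSeriesDataset

__all__ = [
    "VelocityField",
    "barycentric_project",
    "barycentric_project_reverse",
    "compute_velocities",
    "project_velocity",
]


@dataclass
class VelocityField:
    """Per-time, per-cell, per-gene velocities mirroring a dataset's shape.

    ``velocities[k]`` is m x n(t_k); ``schemes[k]`` records which finite
    difference produced it.  ``stimulus_flags`` marks artificial
    predictor-only genes (exempt from normalisation, never targets).
    """

    gene_names: list[str]
    time_points: np.ndarray
    velocities: list[np.ndarray]
    schemes: list[str]
    normalized: bool = False
    stimulus_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        m = len(self.gene_names)
        for k, V in enumerate(self.velocities):
            if V.shape[0] != m:
                raise ValueError(f"velocities[{k}] gene dimension mismatch")
            if not np.all(np.isfinite(V)):
                raise ValueError(f"non-finite velocity at time point {k}")
        if self.stimulus_flags is None:
            self.stimulus_flags = np.zeros(m, dtype=bool)
        else:
            self.stimulus_flags = np.asarray(self.stimulus_flags, dtype=bool)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    def pooled(self) -> np.ndarray:
        """All velocities concatenated over cells: m x sum n(t)."""
        return np.concatenate(self.velocities, axis=1)


def barycentric_project(coupling: Coupling, X_target: np.ndarray) -> np.ndarray:
    """Predicted descendant states of the source cells.

    Column c of the output (an m-vector) is the T-row-weighted average of
    target states: sum_c~ (T_{c c~} / sum_d~ T_{c d~}) x^{t~, c~}.  Every
    prediction lies in the convex hull of the target states.
    """
    T = coupling.T
    if X_target.shape[1] != T.shape[1]:
        raise ValueError("target expression does not match coupling columns")
    rows = T.sum(axis=1)
    bad = np.nonzero(rows <= 0)[0]
    if bad.size:
        raise ValueError(f"zero mass row in coupling for source cell {bad[0]}")
    W = T / rows[:, None]
    return X_target @ W.T


def barycentric_project_reverse(coupling: Coupling, X_source: np.ndarray) -> np.ndarray:
    """Predicted ancestor states of the target cells (column-normalised T)."""
    T = coupling.T
    if X_source.shape[1] != T.shape[0]:
        raise ValueError("source expression does not match coupling rows")
    cols = T.sum(axis=0)
    bad = np.nonzero(cols <= 0)[0]
    if bad.size:
        raise ValueError(f"zero mass column in coupling for target cell {bad[0]}")
    W = T / cols[None, :]
    return X_source @ W


def compute_velocities(
    ds: TimeSeriesDataset, couplings: CouplingSet
) -> VelocityField:
    """Finite-difference gene velocities for every cell at every time point.

    v_forward(x, t_k)  = (proj_{k -> k+1}(x) - x) / (t_{k+1} - t_k)
    v_backward(x, t_k) = (x - proj_{k -> k-1}(x)) / (t_k - t_{k-1})

    Interior points combine the two with non-uniform-gap weights
    (t_k - t_{k-1})/(t_{k+1} - t_{k-1}) on the forward term and
    (t_{k+1} - t_k)/(t_{k+1} - t_{k-1}) on the backward term; with equal
    spacing this reduces to their arithmetic mean.
    """
    N = ds.n_timepoints
    if len(couplings) != N - 1:
        raise ValueError("couplings must cover all consecutive intervals")
    t = ds.time_points
    if np.any(np.diff(t) == 0):
        raise ValueError("coincident time stamps")

    def v_fwd(k: int) -> np.ndarray:
        pred = barycentric_project(couplings[k], ds.expression[k + 1])
        return (pred - ds.expression[k]) / (t[k + 1] - t[k])

    def v_bwd(k: int) -> np.ndarray:
        pred = barycentric_project_reverse(couplings[k - 1], ds.expression[k - 1])
        return (ds.expression[k] - pred) / (t[k] - t[k - 1])

    velocities, schemes = [], []
    for k in range(N):
        if k == 0:
            velocities.append(v_fwd(k))
            schemes.append("forward")
        elif k == N - 1:
            velocities.append(v_bwd(k))
            schemes.append("backward")
        else:
            wf = (t[k] - t[k - 1]) / (t[k + 1] - t[k - 1])
            wb = (t[k + 1] - t[k]) / (t[k + 1] - t[k - 1])
            velocities.append(wf * v_fwd(k) + wb * v_bwd(k))
            schemes.append("centered")
    return VelocityField(
        gene_names=list(ds.gene_names),
        time_points=t,
        velocities=velocities,
        schemes=schemes,
        stimulus_flags=ds.stimulus_flags,
    )


def project_velocity(coupling: Coupling, V_source: np.ndarray) -> np.ndarray:
    """Project source-time velocities onto the target-time cells.

    Column c~ of the result is the descendant-conditional average of
    source velocities: sum_c (T_{c c~} / sum_d T_{d c~}) v(x^{t,c}, t).
    Note the normalisation runs over the *column* of T, unlike the
    row-normalised state projection.
    """
    T = coupling.T
    if V_source.shape[1] != T.shape[0]:
        raise ValueError("velocity matrix does not match coupling rows")
    cols = T.sum(axis=0)
    bad = np.nonzero(cols <= 0)[0]
    if bad.size:
        raise ValueError(f"zero mass column in coupling for target cell {bad[0]}")
    return V_source @ (T / cols[None, :])
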