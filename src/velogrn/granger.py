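"""Granger-causal network inference via per-interval elastic-net regression.

For each consecutive interval (t_k, t_{k+1}), the velocity of every
target gene over the cells observed at t_{k+1} is regressed on the
velocities of all genes projected forward from t_k through the transport
plan (velocities at different times are never observed in the same cell,
so the projection supplies the pairing).  The fit is an elastic net

    min_a  1/(2 n) ||v_{g2} - V_hat^T a||^2
           + lambda (r ||a||_1 + (1 - r)/2 ||a||_2^2),

whose fitted coefficient a_{g1} becomes the signed edge weight
A_{g1,g2}: positive for activation, negative for inhibition.  Interval
matrices are summed into a global network.  Only first-order lags are
regressed (longer compositions degrade and overparameterise).

An artificial "stimulus gene" (velocity 1 at the stimulus time point, 0
elsewhere) can be appended as a predictor-only covariate; stimulus genes
are excluded from velocity normalisation and never regressed as targets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.linear_model import ElasticNet, Ridge

from .coupling import CouplingSet
from .networks import WeightMatrix
from .velocity import VelocityField, project_velocity

__all__ = [
    "GrangerParams",
    "add_stimulus_gene",
    "granger_fit_interval",
    "aggregate_global",
    "granger_network",
]


@dataclass
class GrangerParams:
    """Elastic-net hyperparameters: lam is the overall regularisation
    magnitude, l1_ratio the l1/l2 mix (1 = lasso, 0 = ridge)."""

    lam: float = 1.0
    l1_ratio: float = 0.5
    fit_intercept: bool = False
    max_iter: int = 10000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError(f"l1_ratio must be in [0, 1], got {self.l1_ratio}")


def add_stimulus_gene(
    V: VelocityField, stimulus_time: float, name: str = "stimulus"
) -> VelocityField:
    """Append an artificial predictor-only gene with velocity one at the
    stimulus time point and zero elsewhere."""
    matches = np.nonzero(np.isclose(V.time_points, stimulus_time))[0]
    if matches.size == 0:
        raise ValueError(
            f"stimulus time {stimulus_time} is not one of the time points "
            f"{list(V.time_points)}"
        )
    k_stim = int(matches[0])
    velocities = []
    for k, Vk in enumerate(V.velocities):
        row = np.full((1, Vk.shape[1]), 1.0 if k == k_stim else 0.0)
        velocities.append(np.vstack([Vk, row]))
    return replace(
        V,
        gene_names=list(V.gene_names) + [name],
        velocities=velocities,
        stimulus_flags=np.concatenate([V.stimulus_flags, [True]]),
    )


def granger_fit_interval(
    V_target: np.ndarray,
    V_hat: np.ndarray,
    params: GrangerParams | None = None,
    stimulus_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Elastic-net coefficients A for one interval.

    ``V_target`` (m x n) holds velocities of the cells observed at
    t_{k+1}; ``V_hat`` (m x n) the projected past velocities of the same
    cells.  A_{g1,g2} is the coefficient of predictor g1 in the fit of
    target g2.  Stimulus genes are skipped as targets (their columns stay
    zero).  lam = 0 falls back to ordinary least squares.
    """
    params = params or GrangerParams()
    if V_target.shape != V_hat.shape:
        raise ValueError(
            f"shape mismatch: targets {V_target.shape} vs predictors {V_hat.shape}"
        )
    m, n = V_target.shape
    if stimulus_mask is None:
        stimulus_mask = np.zeros(m, dtype=bool)
    X = V_hat.T  # n cells x m predictors
    A = np.zeros((m, m))
    if params.lam == 0:
        coefs, *_ = np.linalg.lstsq(X, V_target.T, rcond=None)
        A[:, :] = coefs
    elif params.l1_ratio == 0.0:
        # pure l2: closed-form ridge; sklearn's coordinate descent warns here
        model = Ridge(alpha=n * params.lam, fit_intercept=params.fit_intercept)
        model.fit(X, V_target.T)
        A[:, :] = model.coef_.T
    else:
        model = ElasticNet(
            alpha=params.lam,
            l1_ratio=params.l1_ratio,
            fit_intercept=params.fit_intercept,
            max_iter=params.max_iter,
            tol=params.tol,
        )
        for g2 in range(m):
            if stimulus_mask[g2]:
                continue
            model.fit(X, V_target[g2])
            A[:, g2] = model.coef_
    A[:, stimulus_mask] = 0.0
    return A


def aggregate_global(interval_matrices: list[np.ndarray]) -> np.ndarray:
    """Global network as the plain sum of interval matrices."""
    if not interval_matrices:
        raise ValueError("no interval matrices to aggregate")
    return np.sum(interval_matrices, axis=0)


def granger_network(
    V: VelocityField,
    couplings: CouplingSet,
    params: GrangerParams | None = None,
) -> WeightMatrix:
    """Fit all intervals and consolidate into a global signed network."""
    from .corr import normalize_velocity_std

    params = params or GrangerParams()
    if not V.normalized:
        V = normalize_velocity_std(V)
    per_interval: list[np.ndarray] = []
    intervals: list[tuple[float, float]] = []
    for k in range(V.n_timepoints - 1):
        V_hat = project_velocity(couplings[k], V.velocities[k])
        A = granger_fit_interval(
            V.velocities[k + 1], V_hat, params, stimulus_mask=V.stimulus_flags
        )
        per_interval.append(A)
        intervals.append((float(V.time_points[k]), float(V.time_points[k + 1])))
    return WeightMatrix(
        genes=list(V.gene_names),
        matrix=aggregate_global(per_interval),
        method="granger",
        lag=1,
        per_interval=per_interval,
        intervals=intervals,
        stimulus_flags=V.stimulus_flags.copy(),
    )
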