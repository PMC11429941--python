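"""Entropic fused Gromov-Wasserstein coupling of consecutive cell cohorts.

Given cohorts of cells observed at two time points, the transition matrix
T is found as the minimiser over the transport polytope Pi(p, q) of

    (1 - alpha) <T, D>_F
      + alpha * sum_{c,d,c~,d~} L(S_cd, S~_{c~ d~}) T_{c c~} T_{d d~}
      - eps * H(T),

where D is the cross-cohort feature cost (Euclidean or cosine distance of
expression profiles), S and S~ are within-cohort structure costs (geodesic
distances on a kNN graph), L is the Gromov loss (square by default), and
H(T) = -sum T log T is the entropy whose coefficient eps controls
dispersion of the plan.  T_{c c~} is read as the probability mass that
target cell c~ descends from source cell c.

The solver is a projected-gradient scheme: each outer iteration linearises
the Gromov term at the current plan and projects onto Pi(p, q) with a
log-domain Sinkhorn solve (stable for small eps).  Dual potentials are
warm-started across outer iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist
from sklearn.neighbors import kneighbors_graph

from .dataset import TimeSeriesDataset

__all__ = [
    "CouplingParams",
    "Coupling",
    "CouplingSet",
    "feature_cost",
    "structure_cost",
    "solve_fgw",
    "sinkhorn_log",
    "compose_couplings",
    "compose_lagged",
    "fit_all_couplings",
]


@dataclass
class CouplingParams:
    """Hyperparameters of the fused Gromov-Wasserstein coupling.

    alpha blends the feature (Wasserstein) term against the structure
    (Gromov) term; epsilon is the entropic coefficient.  alpha=0.5 and
    epsilon=0.01 are stable defaults across datasets.  The kNN graph used
    for the structure cost has k = max(1, floor(min(knn_cap,
    knn_frac*n(t), knn_frac*n(t~)))) neighbours.
    """

    alpha: float = 0.5
    epsilon: float = 0.01
    knn_cap: int = 50
    knn_frac: float = 0.2
    feature_metric: Literal["euclidean", "cosine"] = "euclidean"
    gw_loss: Literal["square", "absolute"] = "square"
    max_iter: int = 1000
    tol: float = 1e-9
    sinkhorn_max_iter: int = 10000
    sinkhorn_tol: float = 1e-10
    fill_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.feature_metric not in ("euclidean", "cosine"):
            raise ValueError(f"unknown feature metric {self.feature_metric!r}")
        if self.gw_loss not in ("square", "absolute"):
            raise ValueError(f"unknown GW loss {self.gw_loss!r}")


@dataclass
class Coupling:
    """A probability coupling between two cell cohorts.

    T is n(t) x n(t~), nonnegative, with row sums p, column sums q and
    total mass one.
    """

    T: np.ndarray
    p: np.ndarray
    q: np.ndarray
    source_time: float
    target_time: float
    objective: float = float("nan")
    entropy: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.T.shape != (len(self.p), len(self.q)):
            raise ValueError("T shape inconsistent with marginals")

    def marginal_error(self) -> float:
        """Max-norm residual of the row/column marginal constraints."""
        return max(
            float(np.abs(self.T.sum(axis=1) - self.p).max()),
            float(np.abs(self.T.sum(axis=0) - self.q).max()),
        )


@dataclass
class CouplingSet:
    """Ordered couplings for the consecutive intervals (t_k, t_{k+1})."""

    couplings: list[Coupling]

    def __post_init__(self) -> None:
        for a, b in zip(self.couplings, self.couplings[1:]):
            if a.target_time != b.source_time:
                raise ValueError("couplings must cover consecutive intervals")

    def __len__(self) -> int:
        return len(self.couplings)

    def __getitem__(self, k: int) -> Coupling:
        return self.couplings[k]

    def __iter__(self):
        return iter(self.couplings)


# ---------------------------------------------------------------------------
# cost matrices


def feature_cost(
    X_source: np.ndarray, X_target: np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Cross-cohort cost D_{c c~} = d(x^{t,c}, x^{t~,c~}), max-normalised.

    Both matrices are genes x cells with a shared gene order.  The result
    is rescaled so its maximum entry equals one (an all-zero matrix is
    left unscaled).
    """
    if np.isnan(X_source).any() or np.isnan(X_target).any():
        raise ValueError("NaN in expression input")
    D = cdist(X_source.T, X_target.T, metric=metric)
    mx = D.max() if D.size else 0.0
    if mx > 0:
        D = D / mx
    return D


def _knn_for(n_source: int, n_target: int, params: CouplingParams) -> int:
    k = min(params.knn_cap, params.knn_frac * n_source, params.knn_frac * n_target)
    return max(1, int(np.floor(k)))


def structure_cost(
    X: np.ndarray,
    params: CouplingParams | None = None,
    n_other: int | None = None,
) -> np.ndarray:
    """Within-cohort structure cost: geodesic distances on a kNN graph.

    A symmetric (union) kNN graph with Euclidean edge weights is built on
    the cells of one cohort; S holds all-pairs shortest-path distances.
    Pairs in different components are filled with fill_factor times the
    largest finite geodesic.  S is rescaled to max entry one.
    """
    params = params or CouplingParams()
    n = X.shape[1]
    if n == 1:
        return np.zeros((1, 1))
    k = _knn_for(n, n_other if n_other is not None else n, params)
    k = min(k, n - 1)
    G = kneighbors_graph(X.T, n_neighbors=k, mode="distance")
    G = G.maximum(G.T)  # union symmetrisation
    S = shortest_path(G, method="D", directed=False)
    finite = np.isfinite(S)
    if not finite.all():
        fill = S[finite].max() * params.fill_factor
        S[~finite] = fill
    mx = S.max()
    if mx > 0:
        S = S / mx
    return S


# ---------------------------------------------------------------------------
# solver


def _logsumexp(M: np.ndarray, axis: int) -> np.ndarray:
    mx = M.max(axis=axis, keepdims=True)
    out = mx + np.log(np.exp(M - mx).sum(axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


def sinkhorn_log(
    C: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    eps: float,
    tol: float = 1e-10,
    max_iter: int = 10000,
    potentials: tuple[np.ndarray, np.ndarray] | None = None,
    omega: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-stabilised Sinkhorn projection onto Pi(p, q) for cost C.

    Returns (T, f, g) with T = exp((f_i + g_j - C_ij) / eps).  Stable for
    eps several orders of magnitude below the cost scale.  ``potentials``
    warm-starts the dual variables; ``omega`` in [1, 2) applies successive
    overrelaxation to the scaling updates, which sharply reduces the
    iteration count when eps is small relative to the cost range.
    """
    n, m = C.shape
    if potentials is None:
        # epsilon scaling: anneal from a large regularisation down to the
        # target, warm-starting the duals at each level; cuts cold-start
        # iterations when eps is far below the cost scale
        f = np.zeros(n)
        g = np.zeros(m)
        scale = max(float(C.max()), eps)
        level = scale * 0.1
        while level > eps * 2:
            _, f, g = sinkhorn_log(
                C, p, q, level, tol=max(tol, 1e-6), max_iter=200,
                potentials=(f, g), omega=omega,
            )
            level *= 0.25
    else:
        f, g = potentials[0].copy(), potentials[1].copy()

    # stabilised scheme: K holds exp((f_i + g_j - C_ij)/eps); u, v are
    # residual scalings absorbed into (f, g) whenever they overflow.  The
    # exponent is clipped: stale warm-start duals can otherwise overflow
    # exp, and the surplus is removed again by the next scaling updates.
    def _kernel():
        return np.exp(np.minimum((f[:, None] + g[None, :] - C) / eps, 600.0))

    K = _kernel()
    Kt = np.ascontiguousarray(K.T)
    u = np.ones(n)
    v = np.ones(m)
    absorb_at = 1e30
    tiny = 1e-300
    for it in range(max_iter):
        Ktu = Kt @ u
        np.maximum(Ktu, tiny, out=Ktu)
        if omega == 1.0:
            v = q / Ktu
        else:
            v = np.maximum(v, tiny) ** (1.0 - omega) * (q / Ktu) ** omega
        Kv = K @ v
        np.maximum(Kv, tiny, out=Kv)
        if omega == 1.0:
            u = p / Kv
        else:
            u = np.maximum(u, tiny) ** (1.0 - omega) * (p / Kv) ** omega
        if u.max() > absorb_at or v.max() > absorb_at:
            with np.errstate(divide="ignore"):
                f = f + eps * np.log(np.maximum(u, tiny))
                g = g + eps * np.log(np.maximum(v, tiny))
            K = _kernel()
            Kt = np.ascontiguousarray(K.T)
            u = np.ones(n)
            v = np.ones(m)
            continue
        if it % 10 == 9 or it == max_iter - 1:
            err = max(
                float(np.abs(v * (Kt @ u) - q).max()),
                float(np.abs(u * (K @ v) - p).max()),
            )
            if err < tol:
                break
    with np.errstate(divide="ignore"):
        f = f + eps * np.log(np.maximum(u, tiny))
        g = g + eps * np.log(np.maximum(v, tiny))
    T = _kernel()
    return T, f, g


def _gw_constant(S1: np.ndarray, S2: np.ndarray, p: np.ndarray, q: np.ndarray):
    # square-loss decomposition L(a,b) = a^2 + b^2 - 2ab
    return (S1**2) @ p[:, None] + (q[None, :] @ (S2**2).T)


def _gw_gradient(
    S1: np.ndarray,
    S2: np.ndarray,
    T: np.ndarray,
    constC: np.ndarray,
    loss: str,
) -> np.ndarray:
    if loss == "square":
        return 2.0 * (constC - 2.0 * S1 @ T @ S2.T)
    # absolute loss: no low-rank decomposition; O(n^2 m^2) contraction,
    # intended for small cohorts only
    n, m = T.shape
    grad = np.empty((n, m))
    for c in range(n):
        # |S1[c,d] - S2[c~,d~]| contracted against T[d, d~]
        diff = np.abs(S1[c][:, None, None] - S2[None, :, :])  # (n, m, m)
        grad[c] = np.einsum("dyx,dx->y", diff, T)
    return 2.0 * grad


def _gw_energy(S1, S2, T, constC, loss) -> float:
    if loss == "square":
        tens = constC - 2.0 * S1 @ T @ S2.T
        return float((tens * T).sum())
    return float(0.5 * (_gw_gradient(S1, S2, T, constC, loss) * T).sum())


def solve_fgw(
    D: np.ndarray,
    S_source: np.ndarray,
    S_target: np.ndarray,
    p: np.ndarray | None = None,
    q: np.ndarray | None = None,
    params: CouplingParams | None = None,
    source_time: float = 0.0,
    target_time: float = 1.0,
) -> Coupling:
    """Solve the entropic fused Gromov-Wasserstein problem.

    Projected gradient descent: linearise the Gromov term at the current
    plan and re-project with an entropic Sinkhorn solve; stop when the
    relative Frobenius change of the plan falls below ``tol``.  On
    non-convergence the best iterate is returned with ``converged=False``.
    The reported ``objective`` is the fused transport cost (without the
    entropy term); ``entropy`` is H(T).
    """
    params = params or CouplingParams()
    n, m = D.shape
    p = np.full(n, 1.0 / n) if p is None else np.asarray(p, dtype=float)
    q = np.full(m, 1.0 / m) if q is None else np.asarray(q, dtype=float)
    if S_source.shape != (n, n) or S_target.shape != (m, m):
        raise ValueError("structure cost shapes inconsistent with D")
    if np.isnan(D).any():
        raise ValueError("NaN in cost matrix")

    alpha, eps = params.alpha, params.epsilon
    constC = _gw_constant(S_source, S_target, p, q) if alpha > 0 else None

    def _entropic_objective(T: np.ndarray) -> float:
        lin = float((T * D).sum())
        gw = (
            _gw_energy(S_source, S_target, T, constC, params.gw_loss)
            if alpha > 0
            else 0.0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            H = float(-np.sum(np.where(T > 0, T * np.log(T), 0.0)))
        return (1 - alpha) * lin + alpha * gw - eps * H

    T = np.outer(p, q)  # independent coupling: feasible, deterministic
    history: list[float] = []
    pot: tuple[np.ndarray, np.ndarray] | None = None
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        if alpha > 0:
            G = (1 - alpha) * D + alpha * _gw_gradient(
                S_source, S_target, T, constC, params.gw_loss
            )
        else:
            G = D
        T_new, f, g = sinkhorn_log(
            G, p, q, eps,
            tol=params.sinkhorn_tol,
            max_iter=params.sinkhorn_max_iter,
            potentials=pot,
        )
        pot = (f, g)
        delta = np.linalg.norm(T_new - T) / max(np.linalg.norm(T), 1e-300)
        T = T_new
        history.append(_entropic_objective(T))
        if delta < params.tol or alpha == 0:
            converged = True
            break

    np.clip(T, 0.0, None, out=T)
    lin = float((T * D).sum())
    gw = _gw_energy(S_source, S_target, T, constC, params.gw_loss) if alpha > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-np.sum(np.where(T > 0, T * np.log(T), 0.0)))
    return Coupling(
        T=T, p=p, q=q,
        source_time=source_time, target_time=target_time,
        objective=(1 - alpha) * lin + alpha * gw,
        entropy=ent, converged=converged, n_iter=it,
        objective_history=history,
    )


def fgw_objective(coupling: Coupling, D, S_source, S_target, params) -> float:
    """Fused objective value of a given plan (without entropy)."""
    a = params.alpha
    constC = _gw_constant(S_source, S_target, coupling.p, coupling.q)
    lin = float((coupling.T * D).sum())
    gw = _gw_energy(S_source, S_target, coupling.T, constC, params.gw_loss)
    return (1 - a) * lin + a * gw


# ---------------------------------------------------------------------------
# composition and batch fitting


def compose_couplings(first: Coupling, second: Coupling) -> Coupling:
    """Chain two couplings sharing an inner cohort: T_ac = T_ab diag(1/q) T_bc.

    The result has marginals (p_first, q_second) and total mass one.
    Rejects a zero entry in the inner marginal (cannot condition on a
    mass-zero cell).
    """
    if first.T.shape[1] != second.T.shape[0]:
        raise ValueError("inner dimensions do not match")
    if not np.allclose(first.q, second.p, atol=1e-8):
        raise ValueError("inner marginals do not match")
    if np.any(first.q <= 0):
        raise ValueError("zero mass in inner marginal; cannot compose")
    T = first.T @ (second.T / first.q[:, None])
    return Coupling(
        T=T, p=first.p, q=second.q,
        source_time=first.source_time, target_time=second.target_time,
        converged=first.converged and second.converged,
    )


def compose_lagged(couplings: CouplingSet, start: int, lag: int) -> Coupling:
    """Coupling for (t_start, t_{start+lag}) by chaining consecutive plans."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    out = couplings[start]
    for j in range(start + 1, start + lag):
        out = compose_couplings(out, couplings[j])
    return out


def _unique_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of one representative per distinct cell state, the group id
    of every cell, and the group sizes."""
    _, rep, inv, counts = np.unique(
        X.T, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    return rep, inv, counts


def fit_all_couplings(
    ds: TimeSeriesDataset, params: CouplingParams | None = None
) -> CouplingSet:
    """Solve one fused GW problem per consecutive interval of the dataset.

    The dataset should be log-transformed first (costs and velocities are
    both computed on the log scale).  Deterministic for fixed params: the
    solver starts from the independent coupling.

    Cells with exactly identical expression (common after count
    quantisation or dropout) are interchangeable in every term of the
    objective, so each problem is solved over distinct cell states with
    multiplicity-weighted marginals and the plan is expanded afterwards by
    splitting each group's mass equally - exact, and much faster on data
    with many duplicate states.
    """
    params = params or CouplingParams()
    if not ds.transformed:
        raise ValueError(
            "dataset is not log-transformed; apply log1p_transform first"
        )
    n = ds.n_cells
    out = []
    for k in range(ds.n_timepoints - 1):
        try:
            # per the neighbour rule, k depends on both cohort sizes, so the
            # structure costs are interval-specific
            S_src = structure_cost(ds.expression[k], params, n_other=n[k + 1])
            S_tgt = structure_cost(ds.expression[k + 1], params, n_other=n[k])
            D = feature_cost(
                ds.expression[k], ds.expression[k + 1], params.feature_metric
            )
            rep_s, inv_s, cnt_s = _unique_columns(ds.expression[k])
            rep_t, inv_t, cnt_t = _unique_columns(ds.expression[k + 1])
            p = cnt_s / n[k]
            q = cnt_t / n[k + 1]
            c_u = solve_fgw(
                D[np.ix_(rep_s, rep_t)],
                S_src[np.ix_(rep_s, rep_s)],
                S_tgt[np.ix_(rep_t, rep_t)],
                p, q,
                params=params,
                source_time=float(ds.time_points[k]),
                target_time=float(ds.time_points[k + 1]),
            )
            T = c_u.T[np.ix_(inv_s, inv_t)] / np.outer(cnt_s[inv_s], cnt_t[inv_t])
            c = Coupling(
                T=T,
                p=np.full(n[k], 1.0 / n[k]),
                q=np.full(n[k + 1], 1.0 / n[k + 1]),
                source_time=c_u.source_time,
                target_time=c_u.target_time,
                objective=c_u.objective,
                entropy=float(
                    -np.sum(np.where(T > 0, T * np.log(T), 0.0))
                ),
                converged=c_u.converged,
                n_iter=c_u.n_iter,
                objective_history=c_u.objective_history,
            )
        except Exception as exc:  # annotate with the failing interval
            raise RuntimeError(f"coupling failed on interval {k}: {exc}") from exc
        out.append(c)
    return CouplingSet(out)


# ---------------------------------------------------------------------------
# export


def write_coupling(c: Coupling, path: str | Path, params: CouplingParams | None = None) -> None:
    """Write a coupling as dense TSV plus a JSON sidecar of diagnostics."""
    import json

    path = Path(path)
    np.savetxt(path, c.T, delimiter="\t")
    sidecar = {
        "source_time": c.source_time,
        "target_time": c.target_time,
        "objective": c.objective,
        "entropy": c.entropy,
        "converged": c.converged,
        "n_iter": c.n_iter,
        "marginal_error": c.marginal_error(),
    }
    if params is not None:
        sidecar["params"] = {
            "alpha": params.alpha, "epsilon": params.epsilon,
            "feature_metric": params.feature_metric, "gw_loss": params.gw_loss,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
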