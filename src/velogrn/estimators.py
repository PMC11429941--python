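"""Estimator interface for the two network-inference methods.

`LaggedCorrelationGRN` and `GrangerGRN` follow the scikit-learn estimator
protocol (constructor hyperparameters, ``fit``, trailing-underscore
fitted attributes, ``get_params``/``set_params``), with a
:class:`~velogrn.dataset.TimeSeriesDataset` as the input to ``fit``.
Both share the same first stage - entropic fused Gromov-Wasserstein
couplings between consecutive cohorts and finite-difference gene
velocities - and differ in how velocities are turned into a signed
weight matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import corr as _corr
from . import granger as _granger
from .coupling import CouplingParams, fit_all_couplings
from .dataset import TimeSeriesDataset, log1p_transform
from .granger import GrangerParams, add_stimulus_gene
from .networks import WeightMatrix, threshold_edges
from .velocity import compute_velocities

__all__ = ["LaggedCorrelationGRN", "GrangerGRN", "infer_corr", "infer_granger"]


class _BaseVelocityGRN(BaseEstimator):
    """Shared coupling + velocity stage.

    Parameters mirror the coupling hyperparameters; ``stimulus_time``
    optionally appends an artificial predictor-only stimulus gene at that
    time point.  ``fit`` accepts a raw-count dataset (log1p is applied)
    or an already-transformed one.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        epsilon: float = 0.01,
        knn_cap: int = 50,
        knn_frac: float = 0.2,
        feature_metric: str = "euclidean",
        gw_loss: str = "square",
        max_iter: int = 1000,
        tol: float = 1e-9,
        stimulus_time: float | None = None,
    ):
        self.alpha = alpha
        self.epsilon = epsilon
        self.knn_cap = knn_cap
        self.knn_frac = knn_frac
        self.feature_metric = feature_metric
        self.gw_loss = gw_loss
        self.max_iter = max_iter
        self.tol = tol
        self.stimulus_time = stimulus_time

    def _coupling_params(self) -> CouplingParams:
        return CouplingParams(
            alpha=self.alpha,
            epsilon=self.epsilon,
            knn_cap=self.knn_cap,
            knn_frac=self.knn_frac,
            feature_metric=self.feature_metric,
            gw_loss=self.gw_loss,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def fit(self, X: TimeSeriesDataset, y=None):
        """Compute couplings, velocities and the weight matrix."""
        ds = X if X.transformed else log1p_transform(X)
        self.couplings_ = fit_all_couplings(ds, self._coupling_params())
        V = compute_velocities(ds, self.couplings_)
        if self.stimulus_time is not None:
            V = add_stimulus_gene(V, self.stimulus_time)
        self.velocity_field_ = _corr.normalize_velocity_std(V)
        self.weight_matrix_ = self._infer(self.velocity_field_)
        self.gene_names_ = list(self.weight_matrix_.genes)
        return self

    def _infer(self, V) -> WeightMatrix:  # pragma: no cover - abstract
        raise NotImplementedError

    def edge_list(self, **kwargs):
        """Ranked signed edge list from the fitted weight matrix."""
        self._check_fitted()
        return threshold_edges(self.weight_matrix_, **kwargs)

    def _check_fitted(self) -> None:
        if not hasattr(self, "weight_matrix_"):
            raise AttributeError("estimator is not fitted yet; call fit first")


class LaggedCorrelationGRN(_BaseVelocityGRN):
    """GRN inference by OT-weighted time-lagged correlation of velocities.

    Dense, fast, and scales well with gene number; ``lag`` sets the time
    gap (couplings are composed for lag > 1).
    """

    def __init__(
        self,
        alpha: float = 0.5,
        epsilon: float = 0.01,
        knn_cap: int = 50,
        knn_frac: float = 0.2,
        feature_metric: str = "euclidean",
        gw_loss: str = "square",
        max_iter: int = 1000,
        tol: float = 1e-9,
        stimulus_time: float | None = None,
        lag: int = 1,
    ):
        super().__init__(
            alpha=alpha, epsilon=epsilon, knn_cap=knn_cap, knn_frac=knn_frac,
            feature_metric=feature_metric, gw_loss=gw_loss,
            max_iter=max_iter, tol=tol, stimulus_time=stimulus_time,
        )
        self.lag = lag

    def _infer(self, V) -> WeightMatrix:
        return _corr.time_lagged_correlation(V, self.couplings_, lag=self.lag)

    def in_out_degree(self, **kwargs):
        """Per-gene in/out weight ratio (regulator vs target score)."""
        self._check_fitted()
        return _corr.in_out_degree(self.weight_matrix_, **kwargs)


class GrangerGRN(_BaseVelocityGRN):
    """GRN inference by per-interval elastic-net Granger regression.

    Sparse (for l1_ratio near 1) and signed; ``lam`` is the
    regularisation magnitude, ``l1_ratio`` the l1/l2 mix.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        epsilon: float = 0.01,
        knn_cap: int = 50,
        knn_frac: float = 0.2,
        feature_metric: str = "euclidean",
        gw_loss: str = "square",
        max_iter: int = 1000,
        tol: float = 1e-9,
        stimulus_time: float | None = None,
        lam: float = 1.0,
        l1_ratio: float = 0.5,
    ):
        super().__init__(
            alpha=alpha, epsilon=epsilon, knn_cap=knn_cap, knn_frac=knn_frac,
            feature_metric=feature_metric, gw_loss=gw_loss,
            max_iter=max_iter, tol=tol, stimulus_time=stimulus_time,
        )
        self.lam = lam
        self.l1_ratio = l1_ratio

    def _infer(self, V) -> WeightMatrix:
        return _granger.granger_network(
            V, self.couplings_, GrangerParams(lam=self.lam, l1_ratio=self.l1_ratio)
        )


def infer_corr(ds: TimeSeriesDataset, **params) -> WeightMatrix:
    """One-call correlation-mode inference; see :class:`LaggedCorrelationGRN`."""
    return LaggedCorrelationGRN(**params).fit(ds).weight_matrix_


def infer_granger(ds: TimeSeriesDataset, **params) -> WeightMatrix:
    """One-call Granger-mode inference; see :class:`GrangerGRN`."""
    return GrangerGRN(**params).fit(ds).weight_matrix_
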