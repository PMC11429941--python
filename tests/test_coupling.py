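import numpy as np
import pytest
from scipy.optimize import linprog

from velogrn.coupling import (
    Coupling,
    CouplingParams,
    CouplingSet,
    compose_couplings,
    compose_lagged,
    feature_cost,
    fit_all_couplings,
    sinkhorn_log,
    solve_fgw,
    structure_cost,
    _knn_for,
)
from velogrn.dataset import log1p_transform
from conftest import make_dataset


def lp_transport(D, p, q):
    """Exact optimal transport cost by linear programming (oracle)."""
    n, m = D.shape
    A_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i] = 1
        A_eq.append(row.ravel())
    for j in range(m):
        col = np.zeros((n, m))
        col[:, j] = 1
        A_eq.append(col.ravel())
    res = linprog(
        D.ravel(), A_eq=np.array(A_eq), b_eq=np.concatenate([p, q]),
        bounds=(0, None), method="highs",
    )
    assert res.success
    return res.fun


class TestFeatureCost:
    def test_single_pair_normalises_to_one(self):
        D = feature_cost(np.array([[1.0]]), np.array([[4.0]]))
        np.testing.assert_allclose(D, [[1.0]])

    def test_identical_populations_zero_diagonal(self, rng):
        X = rng.normal(size=(3, 6))
        D = feature_cost(X, X)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)

    def test_two_by_two_hand_computed(self):
        X = np.array([[0.0, 3.0]])
        D = feature_cost(X, X)
        np.testing.assert_allclose(D, [[0.0, 1.0], [1.0, 0.0]])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            feature_cost(np.array([[np.nan]]), np.array([[1.0]]))

    def test_cosine_metric(self, rng):
        X = rng.random(size=(4, 5)) + 0.1
        D = feature_cost(X, X, metric="cosine")
        assert D.max() == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)


class TestStructureCost:
    def test_path_graph_geodesics(self):
        # 3 cells on a line at 0, 1, 2 with k=1: geodesics 0,1,2 pre-norm
        X = np.array([[0.0, 1.0, 2.0]])
        S = structure_cost(X, CouplingParams(knn_frac=0.4))  # k=1 for n=3
        np.testing.assert_allclose(S, np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]]) / 2)

    def test_neighbour_count_rule(self):
        assert _knn_for(100, 100, CouplingParams()) == 20
        assert _knn_for(500, 500, CouplingParams()) == 50
        assert _knn_for(4, 4, CouplingParams()) == 1

    def test_disconnected_components_filled_with_max_finite(self):
        # two tight, far-apart pairs; k=1 keeps the components disconnected
        X = np.array([[0.0, 1.0, 100.0, 101.0]])
        S = structure_cost(X, CouplingParams(knn_frac=0.26))
        # within-pair geodesic 1; cross entries = fill_factor * max finite = 1
        assert S[0, 1] == pytest.approx(S[0, 2])
        assert S.max() == pytest.approx(1.0)

    def test_single_cell(self):
        S = structure_cost(np.array([[5.0]]))
        np.testing.assert_array_equal(S, [[0.0]])


class TestSolveFGW:
    def test_single_cell_trivial_plan(self):
        c = solve_fgw(
            np.array([[0.7]]), np.zeros((1, 1)), np.zeros((1, 1)),
            params=CouplingParams(alpha=0.3),
        )
        np.testing.assert_allclose(c.T, [[1.0]])

    def test_small_eps_two_by_two_near_diagonal(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        c = solve_fgw(
            D, np.zeros((2, 2)), np.zeros((2, 2)),
            params=CouplingParams(alpha=0.0, epsilon=1e-3),
        )
        np.testing.assert_allclose(np.diag(c.T), 0.5, atol=1e-3)
        assert c.T[0, 1] < 1e-3 and c.T[1, 0] < 1e-3

    @pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (8, 2)])
    def test_alpha_zero_matches_lp_oracle_within_1pc(self, n, seed):
        rng = np.random.default_rng(seed)
        D = rng.random((n, n))
        p = np.full(n, 1 / n)
        q = np.full(n, 1 / n)
        c = solve_fgw(
            D, np.zeros((n, n)), np.zeros((n, n)), p, q,
            params=CouplingParams(alpha=0.0, epsilon=1e-3, sinkhorn_max_iter=200000),
        )
        exact = lp_transport(D, p, q)
        assert (c.T * D).sum() <= exact * 1.01

    def test_marginals_and_total_mass(self, rng):
        D = rng.random((7, 5))
        S1 = structure_cost(rng.normal(size=(3, 7)), n_other=5)
        S2 = structure_cost(rng.normal(size=(3, 5)), n_other=7)
        c = solve_fgw(D, S1, S2, params=CouplingParams())
        assert c.marginal_error() <= 1e-6
        assert abs(c.T.sum() - 1.0) <= 1e-9
        assert np.all(c.T >= 0)

    def test_objective_non_increasing_across_outer_iterations(self, rng):
        X1 = rng.normal(size=(4, 25))
        X2 = rng.normal(size=(4, 25))
        c = solve_fgw(
            feature_cost(X1, X2),
            structure_cost(X1, n_other=25),
            structure_cost(X2, n_other=25),
            params=CouplingParams(),
        )
        h = np.array(c.objective_history)
        assert len(h) > 1
        assert np.all(np.diff(h) <= 1e-8)

    def test_entropy_non_decreasing_in_epsilon(self, rng):
        X1 = rng.normal(size=(4, 20))
        X2 = rng.normal(size=(4, 20))
        D = feature_cost(X1, X2)
        S1 = structure_cost(X1, n_other=20)
        S2 = structure_cost(X2, n_other=20)
        ents = [
            solve_fgw(D, S1, S2, params=CouplingParams(epsilon=eps)).entropy
            for eps in (0.005, 0.01, 0.05, 0.2)
        ]
        assert np.all(np.diff(ents) >= -1e-9)

    def test_absolute_gw_loss_small_instance(self, rng):
        X1 = rng.normal(size=(2, 6))
        X2 = rng.normal(size=(2, 6))
        c = solve_fgw(
            feature_cost(X1, X2),
            structure_cost(X1, n_other=6),
            structure_cost(X2, n_other=6),
            params=CouplingParams(gw_loss="absolute", max_iter=50),
        )
        assert c.marginal_error() <= 1e-6


class TestSinkhorn:
    def test_tiny_eps_stays_finite_and_feasible(self, rng):
        # eps far below the cost scale exercises the stabilised updates
        C = rng.random((5, 5))
        p = np.full(5, 0.2)
        T, f, g = sinkhorn_log(C, p, p, 1e-4, max_iter=200000)
        assert np.all(np.isfinite(T))
        assert np.abs(T.sum(1) - p).max() < 1e-6
        assert np.abs(T.sum(0) - p).max() < 1e-6


class TestCompose:
    def _unif(self, n):
        return np.full(n, 1 / n)

    def test_identity_composition(self):
        n = 4
        c = Coupling(np.eye(n) / n, self._unif(n), self._unif(n), 0, 1)
        d = Coupling(np.eye(n) / n, self._unif(n), self._unif(n), 1, 2)
        out = compose_couplings(c, d)
        np.testing.assert_allclose(out.T, np.eye(n) / n)
        assert (out.source_time, out.target_time) == (0, 2)

    def test_permutation_composition(self, rng):
        n = 5
        sigma = rng.permutation(n)
        tau = rng.permutation(n)
        P = np.zeros((n, n))
        P[np.arange(n), sigma] = 1 / n
        Q = np.zeros((n, n))
        Q[np.arange(n), tau] = 1 / n
        out = compose_couplings(
            Coupling(P, self._unif(n), self._unif(n), 0, 1),
            Coupling(Q, self._unif(n), self._unif(n), 1, 2),
        )
        expect = np.zeros((n, n))
        expect[np.arange(n), tau[sigma]] = 1 / n
        np.testing.assert_allclose(out.T, expect)

    def test_independent_coupling_is_absorbing(self, rng):
        n, m_, r_ = 4, 3, 5
        p, q, r = self._unif(n), self._unif(m_), self._unif(r_)
        T1 = rng.random((n, m_))
        T1 = T1 / T1.sum() * 1.0
        # project T1 to have marginals (p, q) roughly: use sinkhorn projection
        T1, *_ = sinkhorn_log(-np.log(T1 + 1e-9), p, q, 1.0, max_iter=5000)
        indep = Coupling(np.outer(q, r), q, r, 1, 2)
        out = compose_couplings(Coupling(T1, p, q, 0, 1), indep)
        np.testing.assert_allclose(out.T, np.outer(p, r), atol=1e-8)

    def test_zero_inner_mass_rejected(self):
        c = Coupling(np.array([[0.5, 0.5], [0.5, 0.0]]) / 1.5,
                     np.array([1.0 / 1.5, 0.5 / 1.5]), np.array([1.0 / 1.5, 0.5 / 1.5]), 0, 1)
        d = Coupling(np.array([[1.0, 0.0], [0.0, 0.0]]),
                     np.array([1.0, 0.0]), np.array([1.0, 0.0]), 1, 2)
        with pytest.raises(ValueError, match="zero mass|inner marginals"):
            compose_couplings(c, d)


class TestFitAll:
    def test_requires_log_transform(self):
        with pytest.raises(ValueError, match="log"):
            fit_all_couplings(make_dataset())

    def test_two_time_points_single_coupling(self):
        ds = log1p_transform(make_dataset(ns=(6, 6)))
        cs = fit_all_couplings(ds, CouplingParams(max_iter=50))
        assert len(cs) == 1

    def test_consecutive_interval_labels(self):
        ds = log1p_transform(make_dataset(ns=(5,) * 5))
        cs = fit_all_couplings(ds, CouplingParams(max_iter=30))
        pairs = [(c.source_time, c.target_time) for c in cs]
        assert pairs == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_identical_populations_concentrate_on_diagonal(self, rng):
        X = rng.normal(size=(3, 12)) * 2
        ds = make_dataset(m=3, ns=(12, 12), transformed=True)
        ds.expression = [X, X.copy()]
        cs = fit_all_couplings(ds, CouplingParams(alpha=0.0, epsilon=0.005))
        T = cs[0].T
        diag_mass = np.trace(T)
        assert diag_mass > 1 - diag_mass  # self-matching dominates

    def test_lagged_composition_matches_manual_chain(self):
        ds = log1p_transform(make_dataset(ns=(5, 5, 5)))
        cs = fit_all_couplings(ds, CouplingParams(max_iter=30))
        lag2 = compose_lagged(cs, 0, 2)
        manual = compose_couplings(cs[0], cs[1])
        np.testing.assert_allclose(lag2.T, manual.T)
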