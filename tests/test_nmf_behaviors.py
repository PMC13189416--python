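"""The factorization core: updates, objective, stopping, rank selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import FIXTURE_THETA
from temponmf import nmf_behaviors as nmf
from temponmf import synthetic_data as synth
from temponmf.behavior_analysis import dominant_recovery
from temponmf.io_normalize import TimepointMatrix


def scalar_update_oracle(X, W, H):
    """Element-by-element evaluation of the multiplicative update rules,
    written in plain Python loops, independent of the array implementation."""
    G, T = len(X), len(X[0])
    M = len(W[0])
    XHt = [[sum(X[g][t] * H[m][t] for t in range(T)) for m in range(M)] for g in range(G)]
    HHt = [[sum(H[a][t] * H[b][t] for t in range(T)) for b in range(M)] for a in range(M)]
    WHHt = [[sum(W[g][a] * HHt[a][m] for a in range(M)) for m in range(M)] for g in range(G)]
    W1 = [[W[g][m] * XHt[g][m] / WHHt[g][m] for m in range(M)] for g in range(G)]
    WtX = [[sum(W1[g][m] * X[g][t] for g in range(G)) for t in range(T)] for m in range(M)]
    WtW = [[sum(W1[g][a] * W1[g][b] for g in range(G)) for b in range(M)] for a in range(M)]
    WtWH = [[sum(WtW[m][a] * H[a][t] for a in range(M)) for t in range(T)] for m in range(M)]
    H1 = [[H[m][t] * WtX[m][t] / WtWH[m][t] for t in range(T)] for m in range(M)]
    return W1, H1


class TestInit:
    def test_deterministic(self):
        a = nmf.init(5, 3, 4, seed=2)
        b = nmf.init(5, 3, 4, seed=2)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_uniform_unit_interval(self):
        W, H = nmf.init(200, 10, 50, seed=0)
        for m in (W, H):
            assert m.min() >= 0 and m.max() < 1
        assert abs(np.concatenate([W.ravel(), H.ravel()]).mean() - 0.5) < 0.005


class TestObjective:
    def test_all_ones_closed_form(self):
        W = np.ones((3, 1))
        H = np.ones((1, 4))
        X = W @ H
        assert nmf.objective(X, W, H) == pytest.approx(-12.0, rel=1e-9)

    def test_zero_data(self):
        W = np.full((2, 2), 0.5)
        H = np.full((2, 3), 0.5)
        assert nmf.objective(np.zeros((2, 3)), W, H) == pytest.approx(-(W @ H).sum())

    def test_scaling_identity(self, rng):
        X = rng.uniform(0.1, 2, size=(4, 5))
        W = rng.uniform(0.1, 1, size=(4, 2))
        H = rng.uniform(0.1, 1, size=(2, 5))
        c = 1.7
        lhs = nmf.objective(X, W, c * H, epsilon=0.0)
        rhs = nmf.objective(X, W, H, epsilon=0.0) + X.sum() * np.log(c) - (c - 1) * (W @ H).sum()
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestUpdateStep:
    def test_rank_one_fixed_point(self, rng):
        w = rng.uniform(0.5, 2, size=(6, 1))
        h = rng.uniform(0.5, 2, size=(1, 5))
        X = w @ h
        W1, H1 = nmf.update_step(X, w, h)
        assert np.allclose(W1, w, atol=1e-12)
        assert np.allclose(H1, h, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        """One update on X={{1,2},{3,4}}, W0={{1},{1}}, H0={{1,1}}:
        XHt=(3,7), WHHt=(2,2) so W1=(1.5, 3.5); then W1tX=(12,17) and
        W1tW1·H0=14.5 so H1=(12/14.5, 17/14.5)."""
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        W1, H1 = nmf.update_step(X, np.ones((2, 1)), np.ones((1, 2)))
        assert np.allclose(W1, [[1.5], [3.5]], atol=1e-12)
        assert np.allclose(H1, [[12 / 14.5, 17 / 14.5]], atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scalar_oracle(self, seed):
        r = np.random.default_rng(seed)
        G, M, T = 4, 2, 3
        X = r.uniform(0.1, 3, size=(G, T))
        W = r.uniform(0.1, 1, size=(G, M))
        H = r.uniform(0.1, 1, size=(M, T))
        W1, H1 = nmf.update_step(X, W, H)
        Wo, Ho = scalar_update_oracle(X.tolist(), W.tolist(), H.tolist())
        assert np.allclose(W1, Wo, atol=1e-12)
        assert np.allclose(H1, Ho, atol=1e-12)

    def test_zero_entries_stay_zero(self, rng):
        X = rng.uniform(0, 2, size=(5, 4))
        W = rng.uniform(0, 1, size=(5, 2))
        H = rng.uniform(0, 1, size=(2, 4))
        W[2, 0] = 0.0
        H[1, 3] = 0.0
        W1, H1 = nmf.update_step(X, W, H)
        assert W1[2, 0] == 0.0 and H1[1, 3] == 0.0
        assert (W1 >= 0).all() and (H1 >= 0).all()

    def test_frobenius_gap_never_increases(self):
        r = np.random.default_rng(8)
        for _ in range(100):
            G, M, T = r.integers(2, 8), r.integers(1, 4), r.integers(2, 8)
            X = r.uniform(0, 2, size=(G, T))
            W = r.uniform(0.01, 1, size=(G, M))
            H = r.uniform(0.01, 1, size=(M, T))
            f0 = nmf.frobenius_gap(X, W, H)
            W, H = nmf.update_step(X, W, H)
            assert nmf.frobenius_gap(X, W, H) <= f0 + 1e-9


class TestFrobeniusGapAndRmse:
    def test_exact_factorization_gap_zero(self, rng):
        W = rng.uniform(size=(4, 2))
        H = rng.uniform(size=(2, 5))
        assert nmf.frobenius_gap(W @ H, W, H) == pytest.approx(0.0, abs=1e-12)

    def test_single_entry_difference(self):
        X = np.zeros((2, 2))
        X[0, 1] = 3.0
        assert nmf.frobenius_gap(X, np.zeros((2, 1)), np.zeros((1, 2))) == 3.0

    def test_gap_matches_sum_of_squares_oracle(self, rng):
        X = rng.uniform(size=(5, 4))
        W = rng.uniform(size=(5, 3))
        H = rng.uniform(size=(3, 4))
        D = X - W @ H
        oracle = sum(D[i, j] ** 2 for i in range(5) for j in range(4)) ** 0.5
        assert nmf.frobenius_gap(X, W, H) == pytest.approx(oracle, abs=1e-12)

    def test_rmse_unit_difference(self):
        assert nmf.rmse(np.zeros((2, 2)), np.ones((2, 2))) == pytest.approx(1.0)

    def test_rmse_symmetry_and_triangle(self, rng):
        A, B, C = (rng.uniform(size=(3, 4)) for _ in range(3))
        assert nmf.rmse(A, B) == nmf.rmse(B, A)
        assert nmf.rmse(A, C) <= nmf.rmse(A, B) + nmf.rmse(B, C) + 1e-12
        assert nmf.rmse(A, A) == 0.0

    def test_rmse_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            nmf.rmse(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_gauge_invariance_of_gap(self, rng):
        """Permuting behaviors and rescaling (W P D, D^-1 P^T H) leaves the
        reconstruction, hence the Frobenius gap, unchanged."""
        X = rng.uniform(size=(6, 5))
        W = rng.uniform(size=(6, 3))
        H = rng.uniform(size=(3, 5))
        P = np.eye(3)[[2, 0, 1]]
        D = np.diag([0.5, 2.0, 3.0])
        W2 = W @ P @ D
        H2 = np.linalg.inv(D) @ P.T @ H
        assert nmf.frobenius_gap(X, W2, H2) == pytest.approx(nmf.frobenius_gap(X, W, H))


class TestFit:
    def test_stops_when_gap_change_below_theta(self, rng):
        X = rng.uniform(0, 1, size=(30, 10))
        model = nmf.fit(X, nmf.NMFConfig(M=3, theta=0.05, seed=0))
        assert model.converged
        f = model.frobenius_trace
        assert abs(f[-1] - f[-2]) < 0.05
        assert abs(f[-2] - f[-3]) >= 0.05

    def test_trace_monotone_nonincreasing(self, rng):
        X = rng.uniform(0, 1, size=(40, 12))
        model = nmf.fit(X, nmf.NMFConfig(M=4, theta=1e-6, seed=1, max_iter=500))
        f = np.array(model.frobenius_trace)
        assert np.all(np.diff(f) <= 1e-6)

    def test_requires_scaled_timepoint_matrix(self, rng):
        tm = TimepointMatrix(
            ["g1", "g2"], [("GCSF", 0), ("IL3", 0)], rng.uniform(1, 5, size=(2, 2))
        )
        with pytest.raises(ValueError, match="not max-scaled"):
            nmf.fit(tm, nmf.NMFConfig(M=1))
        model = nmf.fit(tm, nmf.NMFConfig(M=1, theta=1e-3), allow_unscaled=True)
        assert model.W.shape == (2, 1)

    def test_negative_data_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nmf.fit(np.array([[-1.0, 2.0]]), nmf.NMFConfig(M=1))

    def test_exact_rank_matrix_fits_to_near_zero(self, rng):
        W = rng.uniform(0.1, 1, size=(60, 3))
        H = rng.uniform(0.1, 1, size=(3, 10))
        X = W @ H
        model = nmf.fit_restarts(X, nmf.NMFConfig(M=3, theta=1e-8, seed=0), n_restarts=5)
        assert nmf.rmse(model.approximation, X) < 1e-3


class TestSweep:
    def test_bookkeeping(self, rng):
        X = rng.uniform(0, 1, size=(25, 8))
        res = nmf.sweep_M(X, range(2, 7), nmf.NMFConfig(theta=0.01, seed=0))
        assert len(res.rmse_successive) == 4  # |M_range| - 1 consecutive pairs
        assert len(res.rmse_fit) == 5
        assert all(v >= 0 for v in res.rmse_successive.values())
        assert set(res.local_minima) <= set(sorted(res.rmse_successive)[1:-1])

    def test_rank_three_matrix_fit_rmse_vanishes_beyond_rank(self, rng):
        W = rng.uniform(0.1, 1, size=(50, 3))
        H = rng.uniform(0.1, 1, size=(3, 9))
        X = W @ H
        res = nmf.sweep_M(X, range(2, 7), nmf.NMFConfig(theta=1e-8, seed=3))
        for M in (3, 4, 5, 6):
            assert res.rmse_fit[M] < 5e-2
        assert res.rmse_fit[2] > res.rmse_fit[3]

    def test_monotone_range_required(self, rng):
        X = rng.uniform(size=(5, 4))
        with pytest.raises(ValueError):
            nmf.sweep_M(X, [3, 2, 4], nmf.NMFConfig())


class TestRobustness:
    def test_pairwise_count(self, rng):
        X = rng.uniform(0, 1, size=(20, 6))
        res = nmf.robustness(X, nmf.NMFConfig(M=2, theta=0.01, seed=0), n_runs=5)
        assert len(res.rmse_pairwise) == 10
        assert len(res.rmse_to_data) == 5

    def test_identical_seeds_give_zero_pairwise(self, rng):
        X = rng.uniform(0, 1, size=(15, 5))
        cfg = nmf.NMFConfig(M=2, theta=0.01, seed=4)
        a = nmf.fit(X, cfg)
        b = nmf.fit(X, cfg)
        assert nmf.rmse(a.approximation, b.approximation) == 0.0


class TestReconstructGene:
    def _model(self, rng):
        W = rng.uniform(0, 1, size=(4, 3))
        W[2] = 0.0
        W[2, 1] = 0.8
        H = rng.uniform(0, 1, size=(3, 6))
        return nmf.NMFModel(
            W, H, [1.0], [0.0], 1, True, nmf.NMFConfig(M=3),
            gene_ids=["a", "b", "c", "d"],
            labels=[("GCSF", t) for t in range(6)],
        )

    def test_final_curve_is_full_approximation(self, rng):
        model = self._model(rng)
        curves = nmf.reconstruct_gene(model, "b")
        assert np.allclose(curves[-1], model.approximation[1])

    def test_single_weight_gene_constant_after_its_rank(self, rng):
        model = self._model(rng)
        curves = nmf.reconstruct_gene(model, "c", behavior_order=[0, 1, 2])
        assert np.allclose(curves[1], curves[2])
        assert np.allclose(curves[0], 0.0)

    def test_partial_sums_nondecreasing(self, rng):
        model = self._model(rng)
        curves = nmf.reconstruct_gene(model, "a")
        assert np.all(np.diff(curves, axis=0) >= -1e-15)

    def test_unknown_gene(self, rng):
        with pytest.raises(KeyError):
            nmf.reconstruct_gene(self._model(rng), "zz")


class TestFixtureRecovery:
    def test_behaviors_recovered_on_default_fixture(self, dataset, fitted_model):
        """A converged rank-5 fit recovers all planted behaviors (Pearson
        r >= 0.95 after max-normalization and correlation matching) and
        assigns >= 90% of dynamic genes their true dominant behavior."""
        frac, r = dominant_recovery(fitted_model, dataset)
        assert r.min() >= 0.95
        assert frac >= 0.90

    def test_fixture_trace_descends(self, fitted_model):
        f = np.array(fitted_model.frobenius_trace)
        assert np.all(np.diff(f) <= 1e-6)
        assert fitted_model.converged
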