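import numpy as np
import pytest

import beadsig as bs
from beadsig.evaluate import (
    BatchedLoocvEngine,
    DEFAULT_SAB_GRID,
    classification_metrics,
    grid_search,
    loocv_decisions,
    permutation_test,
    roc_and_auc,
)
from beadsig.psvm import fit_psvm, decision_values, predict_labels, kkt_residual
from conftest import centered_problem, psvm_objective


def _separable(seed=0, n_pos=8, n_neg=7, m=6, gap=4.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, m))
    X[:n_pos, :2] += gap
    y = np.r_[np.ones(n_pos), -np.ones(n_neg)].astype(int)
    return X, y


class TestClassificationMetrics:
    def test_study_confusion_counts(self):
        # 26/34 positives and 16/18 negatives correct
        true = np.r_[np.ones(34), -np.ones(18)]
        pred = true.copy()
        pred[:8] = -1    # 8 missed positives
        pred[34:36] = 1  # 2 false positives
        sens, spec, bacc = classification_metrics(true, pred)
        assert (round(sens, 1), round(spec, 1), round(bacc, 1)) == (76.5, 88.9, 82.7)

    def test_perfect_prediction(self):
        true = np.array([1, 1, -1, -1])
        assert classification_metrics(true, true) == (100.0, 100.0, 100.0)

    def test_constant_classifier_has_bacc_fifty(self):
        true = np.r_[np.ones(13), -np.ones(5)]
        pred = np.ones(18)
        assert classification_metrics(true, pred)[2] == 50.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([1, 1], [1, -1])


class TestLoocv:
    def test_matches_naive_refit_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6))
        y = np.array([1, -1, 1, -1, 1, -1, 1, -1, 1, -1])
        ev = loocv_decisions(X, y, C=1.0, eps=0.3, epsitol=1e-8)
        naive = np.empty(10)
        for i in range(10):
            keep = np.arange(10) != i
            model = fit_psvm(X[keep], y[keep], C=1.0, eps=0.3, epsitol=1e-8)
            naive[i] = decision_values(model, X[i][None, :])[0]
        np.testing.assert_allclose(ev.decisions, naive, atol=1e-8)
        np.testing.assert_array_equal(ev.predictions, predict_labels(naive))

    def test_one_decision_per_sample_and_determinism(self):
        X, y = _separable(1)
        e1 = loocv_decisions(X, y, C=1.0, eps=0.5)
        e2 = loocv_decisions(X, y, C=1.0, eps=0.5)
        assert e1.decisions.size == X.shape[0]
        np.testing.assert_array_equal(e1.decisions, e2.decisions)

    def test_metrics_consistent_with_predictions(self):
        X, y = _separable(2)
        ev = loocv_decisions(X, y, C=1.0, eps=0.5)
        sens, spec, bacc = classification_metrics(y, ev.predictions)
        assert (ev.sensitivity, ev.specificity, ev.bacc) == (sens, spec, bacc)

    def test_tiny_class_rejected(self):
        X, _ = _separable(3)
        y = np.r_[1, -np.ones(14)].astype(int)
        with pytest.raises(ValueError):
            loocv_decisions(X, y, C=1.0, eps=0.5)


class TestGridSearch:
    def test_default_sab_grid_has_eight_points(self):
        X, y = _separable(4, n_pos=6, n_neg=6, m=4)
        best, evals = grid_search(X, y)
        assert len(evals) == 8
        assert {(e.C, e.eps) for e in evals} == {
            (C, eps) for eps in (0.25, 0.5, 0.75, 1.0) for C in (1.0, 6.0)}

    def test_single_point_grid(self):
        X, y = _separable(5, n_pos=5, n_neg=5, m=4)
        best, evals = grid_search(X, y, grid=[(1.0, 0.5)])
        assert (best.C, best.eps) == (1.0, 0.5)
        assert len(evals) == 1

    def test_tie_broken_toward_smaller_eps_then_c(self):
        # perfectly separable data ties every grid point at BACC 100
        X, y = _separable(6, gap=50.0)
        best, evals = grid_search(X, y)
        top = max(e.bacc for e in evals)
        tied = [e for e in evals if e.bacc == top]
        assert len(tied) > 1
        assert best.eps == min(e.eps for e in tied)
        assert best.C == min(e.C for e in tied if e.eps == best.eps)


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_and_auc([-2.0, -1.0, 1.0, 2.0], [-1, -1, 1, 1])
        assert roc.auc == 1.0

    def test_all_tied_decisions(self):
        roc = roc_and_auc([0.3] * 6, [1, 1, 1, -1, -1, -1])
        assert roc.auc == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_pair_counting_equals_step_area(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(size=15), 1)  # rounding forces some ties
        y = np.r_[np.ones(8), -np.ones(7)].astype(int)
        roc = roc_and_auc(d, y)
        area = np.trapezoid(roc.tpr, roc.fpr)
        assert roc.auc == pytest.approx(area, abs=1e-12)

    def test_points_monotone_with_endpoints(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=12)
        y = np.r_[np.ones(5), -np.ones(7)].astype(int)
        roc = roc_and_auc(d, y)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([0.1, 0.2], [1, 1])


class TestBatchedEngine:
    def test_solutions_carry_kkt_certificate(self):
        """The batched ADMM solver must satisfy the same optimality
        certificate as the coordinate-descent solver."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 8)) * 3
        y = np.r_[np.ones(6), -np.ones(6)]
        eng = BatchedLoocvEngine(X)
        P = eng.Xc.transpose(0, 2, 1) @ y[eng.train_idx][..., None]
        rho = eng.rho0.copy()
        M = np.linalg.inv(eng.Q + rho[:, None, None] * np.eye(eng.m)).astype(np.float32)
        Z = np.zeros_like(P)
        U = np.zeros_like(P)
        eng._solve(P, 1.0, 0.25, 0.05, rho, M, Z, U)
        for f in range(eng.n):
            keep = np.arange(12) != f
            resid = kkt_residual(X[keep], y[keep], Z[f, :, 0], C=1.0, eps=0.25)
            assert resid <= 0.05
            Q, p = centered_problem(X[keep], y[keep])
            gap = psvm_objective(Q, p, 0.25, Z[f, :, 0]) - psvm_objective(
                Q, p, 0.25, fit_psvm(X[keep], y[keep], 1.0, 0.25, 1e-9).alpha)
            assert gap <= 1e-3 * (1 + abs(psvm_objective(Q, p, 0.25, Z[f, :, 0])))

    def test_agrees_with_cd_grid_search_on_separable_data(self):
        X, y = _separable(8, gap=20.0)
        best, _ = grid_search(X, y)
        eng = BatchedLoocvEngine(X)
        bacc = eng.evaluate(y.astype(float), DEFAULT_SAB_GRID)
        assert bacc[0] == pytest.approx(best.bacc)

    def test_deterministic(self):
        X, y = _separable(9)
        Y = np.stack([y, -y], axis=1).astype(float)
        eng = BatchedLoocvEngine(X)
        b1 = eng.evaluate(Y, DEFAULT_SAB_GRID)
        b2 = BatchedLoocvEngine(X).evaluate(Y, DEFAULT_SAB_GRID)
        np.testing.assert_array_equal(b1, b2)


class TestPermutationTest:
    def test_p_value_formula_and_bounds(self):
        X, y = _separable(10, gap=10.0)
        res = permutation_test(X, y, n_perm=49, seed=3)
        expected = (1 + np.count_nonzero(res.null_stats >= res.observed_stat)) / 50
        assert res.p_value == pytest.approx(expected)
        assert 1 / 50 <= res.p_value <= 1.0
        assert res.null_stats.size == 49

    def test_separable_data_gets_minimal_p(self):
        X, y = _separable(11, gap=30.0)
        res = permutation_test(X, y, n_perm=99, seed=0)
        assert res.observed_stat == 100.0
        assert res.p_value <= 0.05

    def test_label_swap_invariance(self):
        X, y = _separable(12)
        r1 = permutation_test(X, y, n_perm=29, seed=5)
        r2 = permutation_test(X, -y, n_perm=29, seed=5)
        assert r1.observed_stat == pytest.approx(r2.observed_stat)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_full_determinism(self):
        X, y = _separable(13)
        r1 = permutation_test(X, y, n_perm=19, seed=7)
        r2 = permutation_test(X, y, n_perm=19, seed=7)
        np.testing.assert_array_equal(r1.null_stats, r2.null_stats)
        assert r1.p_value == r2.p_value
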