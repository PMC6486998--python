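"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import beadsig as bs


def qp_oracle(Q: np.ndarray, p: np.ndarray, C: float, eps: float) -> np.ndarray:
    """Generic constrained-QP oracle for the P-SVM program.

    Splits alpha = a+ − a− (both in [0, C]) so the L1 term becomes linear and
    the problem is a smooth bound-constrained QP, solved with L-BFGS-B.
    Independent of the package's coordinate-descent solver.
    """
    from scipy.optimize import minimize

    m = p.size

    def fun(z):
        a = z[:m] - z[m:]
        g = Q @ a - p
        val = 0.5 * a @ (Q @ a) - p @ a + eps * z.sum()
        grad = np.concatenate([g + eps, -g + eps])
        return val, grad

    res = minimize(fun, np.zeros(2 * m), jac=True, method="L-BFGS-B",
                   bounds=[(0.0, C)] * (2 * m),
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x[:m] - res.x[m:]


def psvm_objective(Q: np.ndarray, p: np.ndarray, eps: float, alpha: np.ndarray) -> float:
    return float(0.5 * alpha @ (Q @ alpha) - p @ alpha + eps * np.abs(alpha).sum())


def centered_problem(X: np.ndarray, y: np.ndarray):
    """(Q, p) of the P-SVM program for raw training data."""
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc, Xc.T @ np.asarray(y, dtype=float)


def fisher_2x2_oracle(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    from math import comb

    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, n1, n2 = a + b, a + c, b + d
    n = n1 + n2
    denom = comb(n, r1)
    probs = []
    lo, hi = max(0, r1 - n2), min(r1, n1)
    for k in range(lo, hi + 1):
        probs.append(comb(n1, k) * comb(n2, r1 - k) / denom)
    p_obs = comb(n1, a) * comb(n2, b) / denom
    return float(sum(q for q in probs if q <= p_obs * (1 + 1e-12)))


@pytest.fixture(scope="session")
def weak_signal_runs():
    """Paired grid-best LOOCV BACCs (rank vs fixed-1000 binary pipeline) on the
    weak-signal scenario over 20 seeds, computed once and shared.

    Uses the batched LOOCV engine (the same solver the permutation test uses)
    with the default SAB hyperparameter grid.
    """
    from beadsig.evaluate import BatchedLoocvEngine, DEFAULT_SAB_GRID

    rank_bacc, binary_bacc = [], []
    for seed in range(1, 21):
        matrix, meta, nc, _ = bs.weak_signal_scenario(seed)
        y = bs.labels_for(matrix, meta).astype(float)
        Xr = bs.rank_transform(matrix).ranks
        norm = bs.normalize_to_control(matrix, nc, "SUBTRACT")
        Xb = bs.binarize_sab_fixed(norm).values.astype(float)
        rank_bacc.append(BatchedLoocvEngine(Xr).evaluate(y, DEFAULT_SAB_GRID)[0])
        binary_bacc.append(BatchedLoocvEngine(Xb).evaluate(y, DEFAULT_SAB_GRID)[0])
    return np.array(rank_bacc), np.array(binary_bacc)


@pytest.fixture
def small_matrix():
    return bs.AssayMatrix(
        ["s1", "s2"], ["b1", "b2", "b3"],
        np.array([[100.0, 250.0, 1200.0], [80.0, 3000.0, 40.0]]),
        bs.AssayKind.SAB_CLASS1,
    )


@pytest.fixture
def small_nc():
    return bs.NegativeControlProfile(["b1", "b2", "b3"], np.array([50.0, 100.0, 20.0]))
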