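"""Evaluation machinery for the P-SVM classifier: leave-one-out
cross-validation (LOOCV), hyperparameter grid search, classification metrics,
label-permutation significance testing, and ROC/AUC from decision values.

LOOCV refits the model from scratch for every held-out sample — including the
per-fold feature centering — so no statistic of the held-out sample leaks into
its own prediction. The permutation test re-runs the FULL grid search on every
permuted label vector, so the selection over the hyperparameter grid is part
of the null distribution and the p-value stays honest about model selection.

AUC is computed with the Mann-Whitney pair-counting statistic (ties
half-weighted), which is identical to the area under the empirical step ROC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import rankdata

from .psvm import MAX_SWEEPS, _cd_solve, predict_labels

__all__ = [
    "CVEvaluation",
    "PermutationResult",
    "ROCCurve",
    "classification_metrics",
    "loocv_decisions",
    "grid_search",
    "roc_and_auc",
    "permutation_test",
    "LoocvWorkspace",
    "BatchedLoocvEngine",
    "DEFAULT_SAB_GRID",
    "DEFAULT_MAB_GRID",
]

# hyperparameter grids used for the single-antigen and screening panels
DEFAULT_SAB_GRID: list[tuple[float, float]] = [
    (C, eps) for eps in (0.25, 0.5, 0.75, 1.0) for C in (1.0, 6.0)
]
DEFAULT_MAB_GRID: list[tuple[float, float]] = [
    (C, eps) for eps in (8.0, 9.0, 10.0, 11.0) for C in (1.0, 6.0)
]
DEFAULT_EPSITOL = 0.05


@dataclass
class CVEvaluation:
    C: float
    eps: float
    decisions: np.ndarray     # one held-out decision value per sample
    predictions: np.ndarray   # ±1 per sample
    sensitivity: float        # percent
    specificity: float        # percent
    bacc: float               # percent


@dataclass
class PermutationResult:
    observed_stat: float      # BACC percent of the grid-best evaluation
    null_stats: np.ndarray    # grid-best BACC per permutation
    n_perm: int
    seed: int
    p_value: float


@dataclass
class ROCCurve:
    boundaries: np.ndarray        # sorted decision values used as thresholds
    fpr: np.ndarray               # includes the (0,0) and (1,1) endpoints
    tpr: np.ndarray
    auc: float


def classification_metrics(true, predicted) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, balanced accuracy %) of ±1 predictions.

    Full precision is returned; rounding to one decimal happens only in reports.
    """
    t = np.asarray(true, dtype=int).ravel()
    p = np.asarray(predicted, dtype=int).ravel()
    if t.size != p.size:
        raise ValueError("true and predicted must have equal length")
    pos = t == +1
    neg = t == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present in the true labels")
    sens = 100.0 * np.count_nonzero(p[pos] == +1) / pos.sum()
    spec = 100.0 * np.count_nonzero(p[neg] == -1) / neg.sum()
    return sens, spec, (sens + spec) / 2.0


class LoocvWorkspace:
    """Precomputed per-fold quantities for repeated LOOCV on a fixed matrix.

    The fold structure, centering means and Gram matrices Q = XcᵀXc depend on
    X only, not on the labels, so they are shared across grid points and
    label permutations. Each evaluation then only recomputes p = Xcᵀy and the
    coordinate-descent solution per fold.
    """

    def __init__(self, X: np.ndarray):
        X = np.ascontiguousarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("LOOCV requires a 2-D matrix with at least 3 samples")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in feature matrix")
        n, m = X.shape
        self.n, self.m = n, m
        self.X = X
        self.Q = np.empty((n, m, m))
        self.Xc = np.empty((n, n - 1, m))
        self.u = np.empty((n, m))  # centered held-out row per fold
        idx = np.arange(n)
        self.train_idx = np.empty((n, n - 1), dtype=np.int64)
        for i in range(n):
            tr = idx[idx != i]
            self.train_idx[i] = tr
            Xtr = X[tr]
            means = Xtr.mean(axis=0)
            Xc = Xtr - means
            self.Xc[i] = Xc
            self.Q[i] = Xc.T @ Xc
            self.u[i] = X[i] - means

    def decisions(self, y: np.ndarray, C: float, eps: float,
                  epsitol: float = DEFAULT_EPSITOL) -> np.ndarray:
        """Held-out decision value for every sample at one grid point."""
        y = np.asarray(y, dtype=float).ravel()
        if y.size != self.n:
            raise ValueError("one label per sample required")
        for i in range(self.n):
            ytr = y[self.train_idx[i]]
            if np.unique(ytr).size < 2:
                raise ValueError(
                    f"fold {i} loses a class entirely; both classes need >= 2 members"
                )
        return _loocv_kernel(self.Q, self.Xc, self.u, self.train_idx, y,
                             float(C), float(eps), float(epsitol), MAX_SWEEPS)


@njit(cache=True)
def _loocv_kernel(Q, Xc, u, train_idx, y, C, eps, epsitol, max_sweeps):  # pragma: no cover
    n = Q.shape[0]
    d = np.empty(n)
    for i in range(n):
        ytr = y[train_idx[i]]
        p = Xc[i].T @ ytr
        alpha, _, _ = _cd_solve(Q[i], p, C, eps, epsitol, max_sweeps)
        d[i] = u[i] @ alpha + ytr.mean()
    return d


def loocv_decisions(X, y, C: float, eps: float,
                    epsitol: float = DEFAULT_EPSITOL,
                    workspace: LoocvWorkspace | None = None) -> CVEvaluation:
    """Leave-one-out cross-validation at a single (C, eps) grid point.

    Each sample's decision value comes from a model trained without it,
    with centering means recomputed per fold.
    """
    y = np.asarray(y, dtype=int).ravel()
    if workspace is None:
        workspace = LoocvWorkspace(np.asarray(X, dtype=float))
    if np.count_nonzero(y == +1) < 2 or np.count_nonzero(y == -1) < 2:
        raise ValueError("LOOCV requires both classes to have at least 2 members")
    decisions = workspace.decisions(y, C, eps, epsitol)
    predictions = predict_labels(decisions)
    sens, spec, bacc = classification_metrics(y, predictions)
    return CVEvaluation(float(C), float(eps), decisions, predictions, sens, spec, bacc)


def _better(a: CVEvaluation, b: CVEvaluation) -> bool:
    """True if a beats b: higher BACC, ties by smaller eps then smaller C."""
    return (a.bacc, -a.eps, -a.C) > (b.bacc, -b.eps, -b.C)


def grid_search(X, y, grid: list[tuple[float, float]] | None = None,
                epsitol: float = DEFAULT_EPSITOL,
                workspace: LoocvWorkspace | None = None,
                ) -> tuple[CVEvaluation, list[CVEvaluation]]:
    """LOOCV at every (C, eps) grid point; best point = maximal BACC
    (ties broken by smaller eps, then smaller C)."""
    if grid is None:
        grid = DEFAULT_SAB_GRID
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if workspace is None:
        workspace = LoocvWorkspace(np.asarray(X, dtype=float))
    evaluations = [loocv_decisions(X, y, C, eps, epsitol, workspace=workspace)
                   for C, eps in grid]
    best = evaluations[0]
    for ev in evaluations[1:]:
        if _better(ev, best):
            best = ev
    return best, evaluations


def roc_and_auc(decisions, true) -> ROCCurve:
    """ROC from sorted decision values used as boundaries; AUC by the
    Mann-Whitney pair-counting statistic with ties half-weighted.

    At each boundary t, samples with decision value strictly above t are
    called positive. Endpoints (0,0) and (1,1) are always appended.
    """
    d = np.asarray(decisions, dtype=float).ravel()
    t = np.asarray(true, dtype=int).ravel()
    if d.size != t.size:
        raise ValueError("decisions and labels must have equal length")
    pos = t == +1
    neg = t == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    boundaries = np.sort(d)
    tpr = np.array([(d[pos] > b).mean() for b in boundaries])
    fpr = np.array([(d[neg] > b).mean() for b in boundaries])
    # reverse so points run from the strictest boundary (near (0,0)) to the
    # loosest (near (1,1)); endpoints appended
    fpr_pts = np.concatenate(([0.0], fpr[::-1], [1.0]))
    tpr_pts = np.concatenate(([0.0], tpr[::-1], [1.0]))
    # Mann-Whitney AUC: mean rank of positives
    ranks = rankdata(d, method="average")
    u_stat = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u_stat / (n_pos * n_neg)
    return ROCCurve(boundaries, fpr_pts, tpr_pts, float(auc))


class BatchedLoocvEngine:
    """LOOCV grid evaluation for many label vectors at once.

    All label permutations of a fixed feature matrix share the per-fold Gram
    matrices, so the P-SVM program is solved for every (fold, label vector,
    grid point) jointly by ADMM with a pre-factorized x-update: the iteration
    reduces to stacked matrix products over folds × label vectors. Solutions
    carry the same KKT-residual certificate (``epsitol``) as the coordinate-
    descent solver. Used by :func:`permutation_test`, where observed and null
    statistics must come from the identical procedure.
    """

    #: ADMM penalty as a fraction of mean Gram diagonal energy tr(Q)/m
    RHO_SCALE = 0.1
    OVER_RELAX = 1.8
    CHECK_EVERY = 4
    MAX_ITER = 4000
    MAX_RESTARTS = 3

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("LOOCV requires a 2-D matrix with at least 3 samples")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in feature matrix")
        n, m = X.shape
        self.n, self.m = n, m
        idx = np.arange(n)
        self.train_idx = np.stack([idx[idx != i] for i in range(n)])
        Xtr = X[self.train_idx]                       # (n, n-1, m)
        means = Xtr.mean(axis=1)                      # (n, m)
        self.Xc = Xtr - means[:, None, :]             # (n, n-1, m)
        self.Q = self.Xc.transpose(0, 2, 1) @ self.Xc  # (n, m, m)
        self.u = X - means                            # (n, m) centered held-out rows
        tr = np.trace(self.Q, axis1=1, axis2=2)
        self.rho0 = np.maximum(self.RHO_SCALE * tr / m, 1e-12)

    def _solve(self, P, C, eps, epsitol, rho, M, Z, U):
        """ADMM to KKT residual <= epsitol for every fold × chain; in place.

        Converged (fold, chain) problems are frozen so stragglers alone pay
        for further iterations; each problem gets its own certificate.
        """
        restarts = 0
        while True:
            ok = _admm_masked(self.Q, M, P, rho, float(C), float(eps),
                              float(epsitol), Z, U,
                              self.MAX_ITER, self.CHECK_EVERY, self.OVER_RELAX)
            if ok:
                return Z, U
            if restarts >= self.MAX_RESTARTS:
                import warnings

                warnings.warn(
                    "batched P-SVM solver hit its iteration cap; "
                    "KKT residual above epsitol", RuntimeWarning, stacklevel=2)
                return Z, U
            restarts += 1
            rho[:] = rho * 0.5
            M[:] = np.linalg.inv(
                self.Q + rho[:, None, None] * np.eye(self.m)).astype(np.float32)
            U[:] = 0.0

    def evaluate(self, Y: np.ndarray, grid: list[tuple[float, float]],
                 epsitol: float = DEFAULT_EPSITOL) -> np.ndarray:
        """Grid-best LOOCV BACC (percent) for every label-vector column of Y.

        Returns an array of shape (K,) for Y of shape (n, K). Grid-point ties
        are broken exactly as in :func:`grid_search` (smaller eps, then C).
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != self.n:
            raise ValueError("one label per sample required in every column")
        K = Y.shape[1]
        Ytr = Y[self.train_idx]                       # (n, n-1, K)
        if (np.abs(Ytr.sum(axis=1)) >= self.n - 1).any():
            raise ValueError("a fold loses a class entirely")
        P = self.Xc.transpose(0, 2, 1) @ Ytr          # (n, m, K)
        B = Ytr.mean(axis=1)                          # (n, K) offsets per fold
        rho = self.rho0.copy()
        M = np.linalg.inv(self.Q + rho[:, None, None] * np.eye(self.m)).astype(np.float32)

        c_values = sorted({C for C, _ in grid}, reverse=True)
        eps_values = sorted({e for _, e in grid}, reverse=True)
        sol: dict[tuple[float, float], np.ndarray] = {}
        Zsave: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        for ci, C in enumerate(c_values):
            Z = np.zeros((self.n, self.m, K))
            U = np.zeros_like(Z)
            for eps in eps_values:
                if ci > 0:
                    Zp, Up = Zsave[eps]
                    if np.abs(Zp).max() <= C:
                        # the larger-box solution already lies inside this box
                        sol[(C, eps)] = sol[(c_values[ci - 1], eps)]
                        Z, U = Zp.copy(), Up.copy()
                        continue
                    Z, U = np.clip(Zp, -C, C), Up.copy()
                Z, U = self._solve(P, C, eps, epsitol, rho, M, Z, U)
                decisions = np.einsum("fj,fjk->fk", self.u, Z) + B   # (n, K)
                sol[(C, eps)] = decisions
                Zsave[eps] = (Z.copy(), U.copy())

        # BACC per chain and grid point, then grid-best with the tie rule
        pos = Y == 1.0
        neg = ~pos
        n_pos = pos.sum(axis=0)
        n_neg = neg.sum(axis=0)
        order = sorted(grid, key=lambda ce: (ce[1], ce[0]))  # eps asc, C asc
        best = np.full(K, -np.inf)
        for C, eps in order:
            pred_pos = sol[(C, eps)] > 0
            sens = 100.0 * (pred_pos & pos).sum(axis=0) / n_pos
            spec = 100.0 * (~pred_pos & neg).sum(axis=0) / n_neg
            bacc = (sens + spec) / 2.0
            best = np.where(bacc > best, bacc, best)
        return best


@njit(cache=True)
def _admm_masked(Q, M, P, rho, C, eps, epsitol, Z, U,
                 max_iter, check_every, over_relax):  # pragma: no cover - numba
    """Over-relaxed ADMM on every (fold, chain) box-lasso problem, with
    per-problem KKT certificates and freezing of converged problems.

    Q (float64) and M (float32 inverse of Q + rho I): (n, m, m); P, Z, U:
    (n, m, K) float64; rho: (n,). The x-update GEMM runs in float32 for speed;
    the KKT certificate is always evaluated in float64. Returns True when
    every problem reaches KKT residual <= epsitol within max_iter iterations.
    """
    n, m, K = P.shape
    active = np.ones((n, K), dtype=np.bool_)
    n_active = n * K
    for it in range(1, max_iter + 1):
        for f in range(n):
            kact = 0
            for k in range(K):
                if active[f, k]:
                    kact += 1
            if kact == 0:
                continue
            cols = np.empty(kact, dtype=np.int64)
            c = 0
            for k in range(K):
                if active[f, k]:
                    cols[c] = k
                    c += 1
            rf = rho[f]
            kappa = eps / rf
            RHS = np.empty((m, kact), dtype=np.float32)
            for c in range(kact):
                k = cols[c]
                for j in range(m):
                    RHS[j, c] = np.float32(P[f, j, k] + rf * (Z[f, j, k] - U[f, j, k]))
            A = M[f] @ RHS
            for c in range(kact):
                k = cols[c]
                for j in range(m):
                    ar = over_relax * np.float64(A[j, c]) + (1.0 - over_relax) * Z[f, j, k]
                    w = ar + U[f, j, k]
                    if w > kappa:
                        zn = w - kappa
                    elif w < -kappa:
                        zn = w + kappa
                    else:
                        zn = 0.0
                    if zn > C:
                        zn = C
                    elif zn < -C:
                        zn = -C
                    U[f, j, k] += ar - zn
                    Z[f, j, k] = zn
        if it % check_every == 0:
            n_active = 0
            for f in range(n):
                kact = 0
                for k in range(K):
                    if active[f, k]:
                        kact += 1
                if kact == 0:
                    continue
                cols = np.empty(kact, dtype=np.int64)
                c = 0
                for k in range(K):
                    if active[f, k]:
                        cols[c] = k
                        c += 1
                Zf = np.empty((m, kact))
                for c in range(kact):
                    k = cols[c]
                    for j in range(m):
                        Zf[j, c] = Z[f, j, k]
                G = Q[f] @ Zf
                for c in range(kact):
                    k = cols[c]
                    resid = 0.0
                    for j in range(m):
                        gj = G[j, c] - P[f, j, k]
                        zj = Zf[j, c]
                        if zj >= C:
                            v = gj + eps
                            v = v if v > 0.0 else 0.0
                        elif zj <= -C:
                            v = -(gj - eps)
                            v = v if v > 0.0 else 0.0
                        elif zj > 0.0:
                            v = abs(gj + eps)
                        elif zj < 0.0:
                            v = abs(gj - eps)
                        else:
                            v = abs(gj) - eps
                            v = v if v > 0.0 else 0.0
                        if v > resid:
                            resid = v
                            if resid > epsitol:
                                break
                    if resid <= epsitol:
                        active[f, k] = False
                    else:
                        n_active += 1
            if n_active == 0:
                return True
    return n_active == 0


def _kkt_batch_max(G: np.ndarray, Z: np.ndarray, C: float, eps: float) -> float:
    """Max stationarity violation over a stack of solutions (Z exactly sparse
    and box-feasible, as produced by the prox step)."""
    edge = C * (1 - 1e-12)
    v = np.where(
        Z >= edge, np.maximum(G + eps, 0.0),
        np.where(
            Z <= -edge, np.maximum(-(G - eps), 0.0),
            np.where(
                Z > 0, np.abs(G + eps),
                np.where(Z < 0, np.abs(G - eps),
                         np.maximum(np.abs(G) - eps, 0.0)))))
    return float(v.max())


def permutation_test(X, y, grid: list[tuple[float, float]] | None = None,
                     epsitol: float = DEFAULT_EPSITOL,
                     n_perm: int = 1000, seed: int = 0,
                     batch_size: int = 250) -> PermutationResult:
    """Label-permutation significance of the grid-best LOOCV balanced accuracy.

    The full grid search is re-run for every permuted label vector, so the
    hyperparameter selection is inside the null; observed and null statistics
    are computed by the identical batched solver.
    p = (1 + #{null ≥ obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if grid is None:
        grid = DEFAULT_SAB_GRID
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if np.count_nonzero(y == +1) < 2 or np.count_nonzero(y == -1) < 2:
        raise ValueError("both classes need at least 2 members")
    engine = BatchedLoocvEngine(X)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    cols = np.concatenate([y[:, None], perms], axis=1).astype(float)
    stats = np.empty(1 + n_perm)
    for start in range(0, cols.shape[1], batch_size):
        block = cols[:, start:start + batch_size]
        stats[start:start + block.shape[1]] = engine.evaluate(block, grid, epsitol)
    observed, null = float(stats[0]), stats[1:]
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed, null, int(n_perm), int(seed), float(p))
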