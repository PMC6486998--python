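"""Potential Support Vector Machine (P-SVM) — a linear classifier whose dual
multipliers attach to features rather than samples, giving built-in feature
selection.

With column-centered training data ``Xc`` (each feature centered by its
training mean) and labels ``y`` in {−1, +1}, the multipliers ``alpha`` solve
the box-constrained L1-penalized quadratic program

    minimize  F(α) = ½ αᵀ (XcᵀXc) α − (Xcᵀy)ᵀ α + ε Σ_j |α_j|
    subject to −C ≤ α_j ≤ C ,

so ε is an L1 shrinkage that zeroes uninformative features and C a box bound
on each feature's influence. The offset is b = mean(y). Decision values for a
test row u are d(u) = (u − feature_means)ᵀ α + b; the class call is +1 iff
d > 0.

The solver is cyclic coordinate descent with closed-form
soft-threshold-then-clip updates, terminating when the KKT residual of the
program drops below ``epsitol``. It is deterministic and exact in the limit:
its objective matches a generic QP solver to high precision (covered by the
test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "PSVMModel",
    "fit_psvm",
    "decision_values",
    "predict_labels",
    "kkt_residual",
    "MAX_SWEEPS",
]

MAX_SWEEPS = 100_000  # hard stop for coordinate descent


@njit(cache=True)
def _cd_solve(Q, p, C, eps, epsitol, max_sweeps):  # pragma: no cover - numba
    """Cyclic coordinate descent for min ½αᵀQα − pᵀα + eps·Σ|α|, −C ≤ α ≤ C.

    Returns (alpha, n_sweeps, kkt_residual). Maintains g = Qα − p.
    """
    m = Q.shape[0]
    alpha = np.zeros(m)
    g = -p.copy()
    n_sweeps = 0
    resid = np.inf
    while n_sweeps < max_sweeps:
        n_sweeps += 1
        for j in range(m):
            qjj = Q[j, j]
            if qjj <= 0.0:
                continue  # zero-variance feature: alpha stays 0
            # coordinate minimizer: soft-threshold then clip
            z = qjj * alpha[j] - g[j]
            if z > eps:
                t = (z - eps) / qjj
            elif z < -eps:
                t = (z + eps) / qjj
            else:
                t = 0.0
            if t > C:
                t = C
            elif t < -C:
                t = -C
            d = t - alpha[j]
            if d != 0.0:
                alpha[j] = t
                for k in range(m):
                    g[k] += Q[k, j] * d
        resid = _kkt_from_grad(g, alpha, C, eps)
        if resid <= epsitol:
            break
    return alpha, n_sweeps, resid


@njit(cache=True)
def _kkt_from_grad(g, alpha, C, eps):  # pragma: no cover - numba
    """Max stationarity violation of F at alpha given g = Qα − p.

    Subgradient of F at coordinate j is g_j + eps·∂|α_j|. Interior points
    need 0 in that set; at +C the (one-sided) condition is g_j + eps ≤ 0,
    at −C it is g_j − eps ≥ 0.
    """
    m = g.shape[0]
    resid = 0.0
    tol_edge = 1e-12 * (1.0 + C)
    for j in range(m):
        gj = g[j]
        aj = alpha[j]
        if aj > C - tol_edge:
            v = gj + eps
            v = v if v > 0.0 else 0.0
        elif aj < -C + tol_edge:
            v = -(gj - eps)
            v = v if v > 0.0 else 0.0
        elif aj > 0.0:
            v = abs(gj + eps)
        elif aj < 0.0:
            v = abs(gj - eps)
        else:
            v = abs(gj) - eps
            v = v if v > 0.0 else 0.0
        if v > resid:
            resid = v
    return resid


@dataclass
class PSVMModel:
    """Fitted P-SVM: feature multipliers, offset, centering means, diagnostics."""

    alpha: np.ndarray
    b: float
    feature_means: np.ndarray
    C: float
    eps: float
    epsitol: float
    n_sweeps: int = 0
    converged: bool = True
    kkt: float = 0.0

    @property
    def support_features(self) -> np.ndarray:
        """Indices of features with nonzero multipliers."""
        return np.nonzero(self.alpha != 0.0)[0]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alpha": self.alpha.tolist(),
            "b": self.b,
            "feature_means": self.feature_means.tolist(),
            "hyper": {"C": self.C, "eps": self.eps, "epsitol": self.epsitol},
            "diagnostics": {"n_sweeps": self.n_sweeps, "converged": self.converged,
                            "kkt_residual": self.kkt},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PSVMModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            alpha=np.asarray(d["alpha"], dtype=float),
            b=float(d["b"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            C=float(d["hyper"]["C"]),
            eps=float(d["hyper"]["eps"]),
            epsitol=float(d["hyper"]["epsitol"]),
            n_sweeps=int(d["diagnostics"]["n_sweeps"]),
            converged=bool(d["diagnostics"]["converged"]),
            kkt=float(d["diagnostics"]["kkt_residual"]),
        )


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples × features)")
    if y.size != X.shape[0]:
        raise ValueError("one label per sample required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("labels must be ±1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in y")
    return X, y


def fit_psvm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    eps: float,
    epsitol: float = 0.05,
    max_sweeps: int = MAX_SWEEPS,
) -> PSVMModel:
    """Fit the P-SVM on feature matrix X (rank or binary features) and labels ±1.

    Parameters
    ----------
    C : box bound on each multiplier, > 0.
    eps : L1 shrinkage, ≥ 0. ``eps ≥ max_j |Xcᵀy|_j`` yields the all-zero model.
    epsitol : KKT-residual termination tolerance, > 0.
    """
    if X.shape[0] < 2:
        raise ValueError("at least two training samples required")
    if C <= 0 or eps < 0 or epsitol <= 0:
        raise ValueError("require C > 0, eps >= 0, epsitol > 0")
    X, y = _validate_xy(np.asarray(X), np.asarray(y))
    means = X.mean(axis=0)
    Xc = X - means
    Q = Xc.T @ Xc
    p = Xc.T @ y
    alpha, n_sweeps, resid = _cd_solve(
        np.ascontiguousarray(Q), np.ascontiguousarray(p),
        float(C), float(eps), float(epsitol), int(max_sweeps),
    )
    converged = bool(resid <= epsitol)
    if not converged:
        import warnings

        warnings.warn(
            f"P-SVM coordinate descent stopped after {n_sweeps} sweeps with "
            f"KKT residual {resid:.3g} > epsitol {epsitol:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return PSVMModel(alpha=alpha, b=float(y.mean()), feature_means=means,
                     C=float(C), eps=float(eps), epsitol=float(epsitol),
                     n_sweeps=int(n_sweeps), converged=converged, kkt=float(resid))


def decision_values(model: PSVMModel, Xtest: np.ndarray) -> np.ndarray:
    """d(u) = (u − feature_means)ᵀ α + b per test row; centering uses training
    means only, so no test-set statistics leak into the score."""
    Xtest = np.atleast_2d(np.asarray(Xtest, dtype=float))
    if Xtest.shape[1] != model.alpha.size:
        raise ValueError(
            f"feature count mismatch: model has {model.alpha.size}, test data {Xtest.shape[1]}"
        )
    return (Xtest - model.feature_means) @ model.alpha + model.b


def predict_labels(decisions: np.ndarray) -> np.ndarray:
    """+1 iff decision value > 0, else −1 (zero resolves to −1)."""
    d = np.asarray(decisions, dtype=float)
    return np.where(d > 0, 1, -1).astype(int)


def kkt_residual(X: np.ndarray, y: np.ndarray, alpha: np.ndarray,
                 C: float, eps: float) -> float:
    """Stationarity violation of the P-SVM program at ``alpha`` (0 iff optimal).

    Uses the same centering as :func:`fit_psvm` (column means of X).
    """
    X, y = _validate_xy(np.asarray(X), np.asarray(y))
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != X.shape[1]:
        raise ValueError("alpha length must equal the feature count")
    if np.any(np.abs(alpha) > C * (1 + 1e-12)):
        raise ValueError("alpha violates the box constraint |alpha_j| <= C")
    Xc = X - X.mean(axis=0)
    g = Xc.T @ (Xc @ alpha) - Xc.T @ y
    return float(_kkt_from_grad(np.ascontiguousarray(g),
                                np.ascontiguousarray(alpha), float(C), float(eps)))
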