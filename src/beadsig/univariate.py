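"""Single-parameter screening and cohort statistics.

Per-bead Fisher exact tests ask whether any individual reactivity call
separates ACR from control sera. Cohort comparisons reproduce the usual
baseline-characteristics table: Mann-Whitney U for metric variables,
chi-squared or Fisher exact for categorical ones (the r×c Fisher test uses
exhaustive enumeration with the classic probability-ordering two-sided
definition). Confounder scans correlate median-centered bead MFIs with a
covariate such as age or BMI via Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import SampleMetadata
from .preprocess import BinaryReactivityMatrix, CenteredMatrix

__all__ = [
    "BeadTestResult",
    "CohortComparison",
    "ConfounderScan",
    "per_bead_fisher",
    "cohort_compare",
    "confounder_scan",
    "fisher_exact_rxc",
]


@dataclass
class BeadTestResult:
    bead_id: str
    contingency: np.ndarray  # 2×2: rows reactive/non-reactive, cols ACR/control
    p_raw: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        # mirrors the screening convention: raw p at the 0.05 level
        return self.p_raw <= 0.05


def per_bead_fisher(binary: BinaryReactivityMatrix, labels: Sequence[int]) -> list[BeadTestResult]:
    """Two-sided Fisher exact test per bead on the 2×2 reactivity × outcome table,
    with Benjamini–Hochberg adjustment across beads."""
    labels = np.asarray(labels, dtype=int)
    if labels.size != len(binary.sample_ids):
        raise ValueError("one label per sample required")
    pos = labels == +1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("degenerate labels: both classes must be present")
    tables = []
    p_raw = np.empty(len(binary.bead_ids))
    for j in range(len(binary.bead_ids)):
        col = binary.values[:, j]
        a = int(col[pos].sum())          # reactive, ACR
        b = int(col[neg].sum())          # reactive, control
        table = np.array([[a, b], [int(pos.sum()) - a, int(neg.sum()) - b]])
        tables.append(table)
        p_raw[j] = stats.fisher_exact(table, alternative="two-sided")[1]
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    return [
        BeadTestResult(bid, tables[j], float(p_raw[j]), float(p_adj[j]))
        for j, bid in enumerate(binary.bead_ids)
    ]


# ---------------------------------------------------------------------------
# Exact Fisher test for r×c tables (probability-ordering two-sided definition)

def fisher_exact_rxc(table: Iterable[Iterable[int]]) -> float:
    """Exact Fisher test p for an r×c contingency table by full enumeration.

    Enumerates every non-negative integer table with the observed margins and
    sums the hypergeometric probabilities of all tables no more probable than
    the observed one (probability ordering, with a 1 + 1e−7 relative tolerance
    on the comparison, matching the classic convention). Intended for small
    tables — complexity grows combinatorially with margins and cell count.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a non-negative 2-D integer array")
    row = obs.sum(axis=1).astype(int)
    col = obs.sum(axis=0).astype(int)
    n = int(obs.sum())
    if n == 0 or obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0
    lg = np.array([lgamma(k + 1) for k in range(n + 1)])
    # log P(T) = K − Σ_ij lg[T_ij], with K fixed by the margins
    K = lg[row].sum() + lg[col].sum() - lg[n]
    log_p_obs = K - lg[obs].sum()
    cutoff = log_p_obs + np.log1p(1e-7)

    r, c = obs.shape
    total = 0.0

    def fill(i: int, j: int, row_left: int, col_left: np.ndarray, lg_sum: float) -> None:
        nonlocal total
        if i == r - 1:
            # last row forced by the column margins
            lp = K - lg_sum - lg[col_left].sum()
            if lp <= cutoff:
                total += np.exp(lp)
            return
        if j == c - 1:
            # last cell of this row forced by the row margin
            if row_left > col_left[j]:
                return
            col_left[j] -= row_left
            fill(i + 1, 0, int(row[i + 1]), col_left, lg_sum + lg[row_left])
            col_left[j] += row_left
            return
        for v in range(min(row_left, col_left[j]) + 1):
            col_left[j] -= v
            fill(i, j + 1, row_left - v, col_left, lg_sum + lg[v])
            col_left[j] += v

    fill(0, 0, int(row[0]), col.copy(), 0.0)
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# Cohort comparisons (baseline-characteristics table)

@dataclass
class CohortComparison:
    variable: str
    kind: str              # "metric" | "categorical"
    test: str              # "mannwhitney" | "chi2" | "fisher"
    group_summary: dict[str, object]
    p_value: float


def _values_by_class(meta: list[SampleMetadata], variable: str) -> tuple[list, list]:
    acr, ctrl = [], []
    for m in meta:
        if variable not in m.covariates:
            raise KeyError(f"unknown variable {variable!r}")
        v = m.covariates[variable]
        if v is None:
            continue
        (acr if m.label == +1 else ctrl).append(v)
    return acr, ctrl


def cohort_compare(
    meta: list[SampleMetadata],
    spec: list[tuple[str, str, str]],
) -> list[CohortComparison]:
    """Compare the two study groups on each (variable, kind, test) triple.

    Metric variables get mean ± sd summaries and a Mann-Whitney U p; categorical
    ones get per-level counts and a chi-squared or exact Fisher p on the
    2 × levels table.
    """
    out = []
    for variable, kind, test in spec:
        acr, ctrl = _values_by_class(meta, variable)
        if kind == "metric":
            if test != "mannwhitney":
                raise ValueError(f"metric variable {variable!r} requires the Mann-Whitney U test")
            a = np.asarray(acr, dtype=float)
            c = np.asarray(ctrl, dtype=float)
            p = float(stats.mannwhitneyu(a, c, alternative="two-sided").pvalue)
            summary = {
                "ACR": (float(a.mean()), float(a.std(ddof=1))),
                "control": (float(c.mean()), float(c.std(ddof=1))),
            }
        elif kind == "categorical":
            levels = sorted(set(map(str, acr)) | set(map(str, ctrl)))
            counts_a = [sum(str(v) == lv for v in acr) for lv in levels]
            counts_c = [sum(str(v) == lv for v in ctrl) for lv in levels]
            table = np.array([counts_a, counts_c])
            if test == "chi2":
                p = float(stats.chi2_contingency(table, correction=False)[1])
            elif test == "fisher":
                p = fisher_exact_rxc(table)
            else:
                raise ValueError(f"unknown categorical test {test!r}")
            summary = {"levels": levels, "ACR": counts_a, "control": counts_c}
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        out.append(CohortComparison(variable, kind, test, summary, p))
    return out


# ---------------------------------------------------------------------------
# Confounder scan

@dataclass
class ConfounderScan:
    per_bead_r: np.ndarray
    mean_r: float
    sd_r: float
    degenerate: bool = False


def confounder_scan(centered: CenteredMatrix, covariate: Sequence[float]) -> ConfounderScan:
    """Spearman correlation of every (median-centered) bead with a covariate.

    A constant covariate is degenerate: correlations are reported as 0 with a flag.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.size != len(centered.sample_ids):
        raise ValueError("one covariate value per sample required")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate values must be finite")
    n_beads = centered.values.shape[1]
    if np.ptp(cov) == 0:
        r = np.zeros(n_beads)
        return ConfounderScan(r, 0.0, 0.0, degenerate=True)
    r = np.empty(n_beads)
    for j in range(n_beads):
        col = centered.values[:, j]
        if np.ptp(col) == 0:
            r[j] = 0.0
        else:
            r[j] = stats.spearmanr(col, cov).statistic
    return ConfounderScan(r, float(r.mean()), float(r.std(ddof=1)), degenerate=False)
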