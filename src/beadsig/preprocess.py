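"""The two data-processing paths for bead-assay MFI matrices.

Conventional path: normalize each serum profile to a negative-control serum,
then binarize by an MFI threshold — a fixed ratio of 3 for mixed-antigen
screening (MAB), and for single-antigen (SAB) data either a fixed 1000-MFI
cut or a per-sample adaptive cut at 30% of that sample's strongest bead.

Novel path: no normalization or thresholding at all — the raw MFIs of each
serum profile are replaced by their within-sample ranks (average ranks on
ties), which makes downstream classification invariant to any strictly
increasing per-sample distortion of the fluorescence scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core_io import AssayMatrix, NegativeControlProfile

__all__ = [
    "NormalizationMode",
    "BinarizationRule",
    "BinaryReactivityMatrix",
    "RankMatrix",
    "CenteredMatrix",
    "normalize_to_control",
    "binarize_mab",
    "binarize_sab_fixed",
    "binarize_sab_adaptive",
    "rank_transform",
    "median_center",
]


class NormalizationMode(str, enum.Enum):
    RATIO = "RATIO"        # sample / NC, per bead (MAB "background ratio")
    SUBTRACT = "SUBTRACT"  # sample − NC, floored at 0 (SAB "baseline normalized")


class BinarizationRule(str, enum.Enum):
    MAB_RATIO = "MAB_RATIO"
    SAB_FIXED = "SAB_FIXED"
    SAB_ADAPTIVE = "SAB_ADAPTIVE"


@dataclass
class BinaryReactivityMatrix:
    """0/1 reactivity calls plus the record of the threshold that made them.

    ``thresholds`` holds one applied threshold per sample: the global value
    repeated for the fixed rules, the per-sample cut for the adaptive rule.
    """

    sample_ids: list[str]
    bead_ids: list[str]
    values: np.ndarray
    rule: BinarizationRule
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.thresholds = np.asarray(self.thresholds, dtype=float).ravel()
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary reactivity values must be exactly 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.thresholds.size != len(self.sample_ids):
            raise ValueError("one threshold per sample required")


@dataclass
class RankMatrix:
    """Within-sample ranks of bead MFIs (ties averaged), range [1, n_beads]."""

    sample_ids: list[str]
    bead_ids: list[str]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)


def _check_beads(matrix: AssayMatrix, nc: NegativeControlProfile) -> None:
    if list(matrix.bead_ids) != list(nc.bead_ids):
        raise ValueError("bead sets of matrix and negative control differ")


def normalize_to_control(
    matrix: AssayMatrix,
    nc: NegativeControlProfile,
    mode: NormalizationMode | str,
) -> AssayMatrix:
    """Normalize each sample profile to the negative-control serum.

    RATIO divides bead-wise (requires strictly positive control values);
    SUBTRACT subtracts bead-wise and floors at zero.
    """
    mode = NormalizationMode(mode)
    _check_beads(matrix, nc)
    if mode is NormalizationMode.RATIO:
        zero = np.nonzero(nc.mfi <= 0)[0]
        if zero.size:
            raise ValueError(
                f"RATIO normalization undefined: negative-control MFI is 0 for bead "
                f"{matrix.bead_ids[zero[0]]!r}"
            )
        values = matrix.mfi / nc.mfi
    else:
        values = np.maximum(matrix.mfi - nc.mfi, 0.0)
    return AssayMatrix(matrix.sample_ids, matrix.bead_ids, values, matrix.assay_kind)


def binarize_mab(normalized: AssayMatrix, ratio_threshold: float = 3.0) -> BinaryReactivityMatrix:
    """A bead is positive when its background ratio strictly exceeds the threshold (3)."""
    if ratio_threshold < 0:
        raise ValueError("ratio_threshold must be non-negative")
    values = (normalized.mfi > ratio_threshold).astype(np.int8)
    thresholds = np.full(normalized.n_samples, float(ratio_threshold))
    return BinaryReactivityMatrix(normalized.sample_ids, normalized.bead_ids,
                                  values, BinarizationRule.MAB_RATIO, thresholds)


def binarize_sab_fixed(normalized: AssayMatrix, threshold: float = 1000.0) -> BinaryReactivityMatrix:
    """A bead is positive when its baseline-normalized MFI strictly exceeds the
    fixed cut (default 1000 MFI)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = (normalized.mfi > threshold).astype(np.int8)
    thresholds = np.full(normalized.n_samples, float(threshold))
    return BinaryReactivityMatrix(normalized.sample_ids, normalized.bead_ids,
                                  values, BinarizationRule.SAB_FIXED, thresholds)


def binarize_sab_adaptive(normalized: AssayMatrix, fraction: float = 0.30) -> BinaryReactivityMatrix:
    """Per-sample adaptive cut: positive when the MFI strictly exceeds
    ``fraction`` × that sample's strongest bead."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    row_max = normalized.mfi.max(axis=1)
    dead = np.nonzero(row_max <= 0)[0]
    if dead.size:
        raise ValueError(
            f"adaptive threshold undefined for sample {normalized.sample_ids[dead[0]]!r}: "
            "all normalized MFIs are zero"
        )
    thresholds = fraction * row_max
    values = (normalized.mfi > thresholds[:, None]).astype(np.int8)
    return BinaryReactivityMatrix(normalized.sample_ids, normalized.bead_ids,
                                  values, BinarizationRule.SAB_ADAPTIVE, thresholds)


def rank_transform(raw: AssayMatrix, per_bead: bool = False) -> RankMatrix:
    """Rank-transform raw MFIs: within each sample by default (each serum
    profile becomes the ranks 1..n_beads of its beads, average ranks on ties).

    ``per_bead=True`` ranks each bead column across samples instead.
    """
    axis = 0 if per_bead else 1
    ranks = rankdata(raw.mfi, method="average", axis=axis)
    return RankMatrix(raw.sample_ids, raw.bead_ids, ranks)


def median_center(matrix: AssayMatrix) -> "CenteredMatrix":
    """Subtract each bead's across-sample median; used for confounder scans.

    Centered values can be negative, so the result is a :class:`CenteredMatrix`
    rather than an :class:`AssayMatrix`.
    """
    if matrix.n_samples < 1:
        raise ValueError("median centering requires at least one sample")
    centered = matrix.mfi - np.median(matrix.mfi, axis=0, keepdims=True)
    return CenteredMatrix(matrix.sample_ids, matrix.bead_ids, centered)


@dataclass
class CenteredMatrix:
    """Median-centered MFI matrix (values may be negative)."""

    sample_ids: list[str]
    bead_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
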