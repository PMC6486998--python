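"""Data model, file I/O and validation for antigen-bead assay analyses.

The central container is :class:`AssayMatrix`, a sample-by-bead matrix of
median fluorescence intensities (MFI) from a Luminex bead assay, either a
mixed-antigen screening panel (MAB) or a single-antigen panel (SAB).
Per-sample outcome labels and covariates live in :class:`SampleMetadata`;
a negative-control serum profile used for normalization lives in
:class:`NegativeControlProfile`.

Files are plain rectangular delimited text (UTF-8, TSV or CSV accepted,
TSV written): header row of bead IDs, first column of sample IDs.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayKind",
    "AssayMatrix",
    "SampleMetadata",
    "NegativeControlProfile",
    "ValidationReport",
    "FormatError",
    "read_mfi_table",
    "write_mfi_table",
    "read_metadata",
    "write_metadata",
    "read_negative_control",
    "write_negative_control",
    "validate_dataset",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


class AssayKind(str, enum.Enum):
    MAB = "MAB"
    SAB_CLASS1 = "SAB_CLASS1"
    SAB_CLASS2 = "SAB_CLASS2"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FormatError(f"duplicate {what}: {', '.join(dups)}")


@dataclass
class AssayMatrix:
    """Sample × bead MFI matrix with its assay kind.

    Invariants enforced at construction: matrix shape matches the ID lists,
    all values are finite and non-negative, IDs are unique.
    """

    sample_ids: list[str]
    bead_ids: list[str]
    mfi: np.ndarray
    assay_kind: AssayKind

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.bead_ids = [str(b) for b in self.bead_ids]
        self.mfi = np.asarray(self.mfi, dtype=float)
        self.assay_kind = AssayKind(self.assay_kind)
        if self.mfi.ndim != 2 or self.mfi.shape != (len(self.sample_ids), len(self.bead_ids)):
            raise FormatError(
                f"matrix shape {self.mfi.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.bead_ids)} beads"
            )
        _check_unique(self.sample_ids, "sample IDs")
        _check_unique(self.bead_ids, "bead IDs")
        if not np.all(np.isfinite(self.mfi)):
            r, c = np.argwhere(~np.isfinite(self.mfi))[0]
            raise FormatError(
                f"non-finite MFI at sample {self.sample_ids[r]!r}, bead {self.bead_ids[c]!r}"
            )
        if np.any(self.mfi < 0):
            r, c = np.argwhere(self.mfi < 0)[0]
            raise FormatError(
                f"negative MFI {self.mfi[r, c]} at sample {self.sample_ids[r]!r}, "
                f"bead {self.bead_ids[c]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_beads(self) -> int:
        return len(self.bead_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mfi, index=self.sample_ids, columns=self.bead_ids)


@dataclass
class SampleMetadata:
    """Outcome label and covariates for one sample.

    ``label`` is +1 for acute cellular rejection (ACR), −1 for control.
    """

    sample_id: str
    label: int
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label = int(self.label)
        if self.label not in (+1, -1):
            raise FormatError(f"label must be +1 or -1, got {self.label}")


@dataclass
class NegativeControlProfile:
    """One negative-control serum MFI value per bead (e.g. OLI.NS for SAB)."""

    bead_ids: list[str]
    mfi: np.ndarray
    source: str = "NC serum"

    def __post_init__(self) -> None:
        self.bead_ids = [str(b) for b in self.bead_ids]
        self.mfi = np.asarray(self.mfi, dtype=float).ravel()
        if len(self.bead_ids) != self.mfi.size:
            raise FormatError("negative control bead count does not match value count")
        _check_unique(self.bead_ids, "bead IDs")
        if not np.all(np.isfinite(self.mfi)) or np.any(self.mfi < 0):
            raise FormatError("negative control MFIs must be finite and non-negative")


# ---------------------------------------------------------------------------
# File I/O

def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,").delimiter
    except csv.Error:
        return "\t" if "\t" in head else ","


def _read_rectangular(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    # check header duplicates on the raw line; pandas would silently rename them
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_dup_named(header, "bead IDs", path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as e:  # ragged rows
        raise FormatError(f"{path.name}: malformed table ({e})") from e
    df.columns = header
    _check_dup_named(list(df.index), "sample IDs", path)
    return df


def _check_dup_named(ids: Sequence[str], what: str, path: Path) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FormatError(f"{path.name}: duplicate {what}: {', '.join(map(str, dups))}")


def read_mfi_table(path: str | Path, assay_kind: AssayKind | str) -> AssayMatrix:
    """Read a sample × bead MFI table (TSV or CSV, delimiter auto-detected).

    First column holds sample IDs, the header row holds bead IDs. Missing,
    non-numeric or negative cells are format errors with coordinates.
    """
    path = Path(path)
    df = _read_rectangular(path)
    values = np.empty(df.shape, dtype=float)
    for i, (sid, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            txt = str(cell).strip().replace("−", "-")  # unicode minus
            if txt == "":
                raise FormatError(
                    f"{path.name}: missing value at sample {sid!r}, bead {df.columns[j]!r}"
                )
            try:
                v = float(txt)
            except ValueError:
                raise FormatError(
                    f"{path.name}: non-numeric value {cell!r} at sample {sid!r}, "
                    f"bead {df.columns[j]!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path.name}: negative MFI {v} at sample {sid!r}, bead {df.columns[j]!r}"
                )
            values[i, j] = v
    return AssayMatrix(list(df.index), list(df.columns), values, AssayKind(assay_kind))


def write_mfi_table(matrix: AssayMatrix, path: str | Path) -> None:
    """Write an MFI table as TSV (values formatted with up to 6 significant digits)."""
    df = matrix.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


_LABEL_TOKENS = {
    "ACR": +1, "acr": +1, "+1": +1, "1": +1,
    "control": -1, "Control": -1, "CONTROL": -1, "-1": -1, "−1": -1,
}


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata: columns ``sample_id``, ``label``, optional covariates.

    Labels may be written as ACR/control or +1/−1.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if "sample_id" not in cols or "label" not in cols:
        raise FormatError(f"{path.name}: metadata requires 'sample_id' and 'label' columns")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df["sample_id"][df["sample_id"].duplicated()]))
        raise FormatError(f"{path.name}: duplicate sample IDs: {', '.join(dups)}")
    records = []
    covar_cols = [c for c in cols if c not in ("sample_id", "label")]
    for _, row in df.iterrows():
        tok = str(row["label"]).strip()
        if tok not in _LABEL_TOKENS:
            raise FormatError(f"{path.name}: unknown label {tok!r} for sample {row['sample_id']!r}")
        covs: dict[str, object] = {}
        for c in covar_cols:
            raw = str(row[c]).strip()
            if raw == "":
                covs[c] = None
                continue
            try:
                covs[c] = float(raw)
            except ValueError:
                covs[c] = raw
        records.append(SampleMetadata(str(row["sample_id"]), _LABEL_TOKENS[tok], covs))
    return records


def write_metadata(records: list[SampleMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {"sample_id": r.sample_id,
                                  "label": "ACR" if r.label == 1 else "control"}
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_negative_control(path: str | Path, source: str = "NC serum") -> NegativeControlProfile:
    """Read a one-row negative-control profile (same layout as an MFI table)."""
    df = _read_rectangular(Path(path))
    if df.shape[0] != 1:
        raise FormatError(f"negative control file must contain exactly one row, got {df.shape[0]}")
    vals = pd.to_numeric(df.iloc[0], errors="coerce")
    if vals.isna().any():
        bad = df.columns[vals.isna()][0]
        raise FormatError(f"non-numeric negative-control value for bead {bad!r}")
    return NegativeControlProfile(list(df.columns), vals.to_numpy(float), source=source)


def write_negative_control(nc: NegativeControlProfile, path: str | Path) -> None:
    df = pd.DataFrame([nc.mfi], index=[nc.source], columns=nc.bead_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Validation

@dataclass
class ValidationReport:
    passed: bool
    n_acr: int
    n_ctrl: int
    n_beads: int
    unmatched_matrix_ids: list[str]
    unmatched_meta_ids: list[str]
    messages: list[str]

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"[{status}] {self.n_acr} ACR + {self.n_ctrl} control samples, "
                 f"{self.n_beads} beads"]
        lines += [f"  - {m}" for m in self.messages]
        return "\n".join(lines)


def validate_dataset(matrix: AssayMatrix, meta: list[SampleMetadata]) -> ValidationReport:
    """Check that every matrix sample has exactly one metadata record and that
    both outcome classes are represented."""
    by_id = {m.sample_id: m for m in meta}
    unmatched_matrix = [s for s in matrix.sample_ids if s not in by_id]
    matrix_set = set(matrix.sample_ids)
    unmatched_meta = [m.sample_id for m in meta if m.sample_id not in matrix_set]
    labels = [by_id[s].label for s in matrix.sample_ids if s in by_id]
    n_acr = sum(1 for v in labels if v == +1)
    n_ctrl = sum(1 for v in labels if v == -1)
    messages: list[str] = []
    passed = True
    if unmatched_matrix:
        passed = False
        messages.append("samples without metadata: " + ", ".join(unmatched_matrix))
    if n_acr == 0 or n_ctrl == 0:
        passed = False
        messages.append("degenerate class structure: both ACR and control samples required")
    if unmatched_meta:
        messages.append("metadata records not in matrix (ignored): " + ", ".join(unmatched_meta))
    return ValidationReport(passed, n_acr, n_ctrl, matrix.n_beads,
                            unmatched_matrix, unmatched_meta, messages)


def labels_for(matrix: AssayMatrix, meta: list[SampleMetadata]) -> np.ndarray:
    """Label vector (±1) aligned to the matrix sample order.

    Raises if validation fails; this is the gate every pipeline entry point uses.
    """
    report = validate_dataset(matrix, meta)
    if not report.passed:
        raise FormatError("dataset validation failed:\n" + str(report))
    by_id = {m.sample_id: m.label for m in meta}
    return np.array([by_id[s] for s in matrix.sample_ids], dtype=int)
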