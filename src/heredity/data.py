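"""Observation matrices and their canonical delimited-text format.

The central data object is the observation matrix ``P``: one row per final
system state (each obtained under a distinct selection pressure), one column
per investigator-chosen feature.  Everything downstream — the eigenvalue-gap
metric and all three simulators — produces or consumes this container.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ObservationMatrix", "read_matrix", "write_matrix"]


@dataclass
class ObservationMatrix:
    """A matrix of end-state observations.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_features)
        Unitless feature scores; all entries must be finite.
    feature_labels : list of str, optional
        Column labels, length ``n_features``.
    row_meta : sequence, optional
        Per-row tag, e.g. the selection-pressure or species identity that
        produced the row.  Carried along but never used by the metric.
    """

    values: np.ndarray
    feature_labels: Optional[list] = None
    row_meta: Optional[Sequence] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("observation matrix must be 2-dimensional")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("observation matrix must have at least one row and column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observation matrix contains non-finite entries")
        if self.feature_labels is not None:
            self.feature_labels = list(self.feature_labels)
            if len(self.feature_labels) != self.values.shape[1]:
                raise ValueError("feature_labels length does not match column count")
        if self.row_meta is not None and len(self.row_meta) != self.values.shape[0]:
            raise ValueError("row_meta length does not match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_rows(self, index) -> "ObservationMatrix":
        """Return a new matrix with the selected rows (metadata preserved)."""
        index = np.asarray(index)
        meta = None
        if self.row_meta is not None:
            meta = [self.row_meta[i] for i in index]
        return ObservationMatrix(self.values[index], self.feature_labels, meta)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ObservationMatrix":
        return cls(frame.to_numpy(dtype=float), feature_labels=[str(c) for c in frame.columns])

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.feature_labels
        if cols is None:
            cols = [f"f{i}" for i in range(self.n_features)]
        return pd.DataFrame(self.values, columns=cols)


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_matrix(path, delimiter: Optional[str] = None) -> ObservationMatrix:
    """Read a delimited numeric matrix (CSV by default, TSV by extension).

    An optional single header row of feature labels is auto-detected: if any
    cell of the first non-empty row does not parse as a number, that row is
    taken as the header.  Ragged or non-numeric data rows raise a
    ``ValueError`` naming the offending line.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    rows: list[list[str]] = []
    line_numbers: list[int] = []
    with open(path, newline="") as handle:
        for lineno, record in enumerate(csv.reader(handle, delimiter=sep), start=1):
            if not record or all(cell.strip() == "" for cell in record):
                continue
            rows.append([cell.strip() for cell in record])
            line_numbers.append(lineno)
    if not rows:
        raise ValueError(f"{path}: no data rows")

    def _numeric(cells: list[str]) -> bool:
        try:
            [float(c) for c in cells]
            return True
        except ValueError:
            return False

    labels = None
    if not _numeric(rows[0]):
        labels = rows[0]
        rows = rows[1:]
        line_numbers = line_numbers[1:]
    if not rows:
        raise ValueError(f"{path}: header but no data rows")

    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=float)
    for k, (cells, lineno) in enumerate(zip(rows, line_numbers)):
        if len(cells) != width:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {width}"
            )
        try:
            data[k] = [float(c) for c in cells]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from exc
    if labels is not None and len(labels) != width:
        raise ValueError(f"{path}: header has {len(labels)} fields, data rows have {width}")
    return ObservationMatrix(data, feature_labels=labels)


def write_matrix(matrix: ObservationMatrix, path, delimiter: Optional[str] = None) -> None:
    """Write a matrix to delimited text; round-trips at full float precision."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        if matrix.feature_labels is not None:
            writer.writerow(matrix.feature_labels)
        for row in matrix.values:
            writer.writerow([repr(float(v)) for v in row])
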