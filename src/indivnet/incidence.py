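"""Binary individual x food-item incidence matrices.

The central container of the package: rows are individual consumers (one
retained sample per individual per season), columns are food-item
categories, and a cell is 1 when that individual's sample contained that
item.  Matrices are strictly binary -- interactions are recorded as
occurrences, never counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IncidenceMatrix", "IncidenceError"]


class IncidenceError(ValueError):
    """Raised for malformed incidence matrices (non-binary cells, duplicate labels...)."""


@dataclass(frozen=True)
class IncidenceMatrix:
    """Labelled binary matrix of individual-resource interactions.

    Parameters
    ----------
    row_labels : tuple of str
        Unique individual identifiers, one per matrix row.
    col_labels : tuple of str
        Unique food-item category labels, one per column.
    values : numpy.ndarray
        Binary (0/1) array of shape ``(len(row_labels), len(col_labels))``.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "row_labels", tuple(str(r) for r in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(c) for c in self.col_labels))
        if arr.ndim != 2:
            raise IncidenceError(f"incidence values must be 2-D, got {arr.ndim}-D")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise IncidenceError(
                f"shape {arr.shape} does not match labels "
                f"({len(self.row_labels)} rows, {len(self.col_labels)} cols)"
            )
        bad = np.argwhere((arr != 0) & (arr != 1))
        if bad.size:
            i, j = bad[0]
            raise IncidenceError(
                f"non-binary cell at (row {self.row_labels[i]!r}, "
                f"col {self.col_labels[j]!r})"
            )
        if len(set(self.row_labels)) != len(self.row_labels):
            raise IncidenceError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise IncidenceError("duplicate column labels")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    # -- basic descriptors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_links(self) -> int:
        """Number of realized interactions (cells equal to 1)."""
        return int(self.values.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and bool(np.array_equal(self.values, other.values))
        )

    def __hash__(self) -> int:  # frozen dataclass with array payload
        return hash((self.row_labels, self.col_labels, self.values.tobytes()))

    # -- transforms --------------------------------------------------------

    def prune(self) -> "IncidenceMatrix":
        """Drop all-zero rows and columns, preserving label order.

        Raises
        ------
        IncidenceError
            If pruning would leave an empty matrix.
        """
        keep_r = self.values.sum(axis=1) > 0
        keep_c = self.values.sum(axis=0) > 0
        if not keep_r.any() or not keep_c.any():
            raise IncidenceError("matrix has no interactions after pruning")
        return IncidenceMatrix(
            tuple(l for l, k in zip(self.row_labels, keep_r) if k),
            tuple(l for l, k in zip(self.col_labels, keep_c) if k),
            self.values[np.ix_(keep_r, keep_c)],
        )

    # -- serialization -----------------------------------------------------

    def to_csv(self, path: str | Path, index_name: str = "individual") -> None:
        """Write as a labelled CSV (first column = individual id, header = items)."""
        df = pd.DataFrame(self.values, index=list(self.row_labels), columns=list(self.col_labels))
        df.index.name = index_name
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IncidenceMatrix":
        """Read a labelled 0/1 CSV written by :meth:`to_csv`.

        Non-binary cells and duplicated labels raise :class:`IncidenceError`
        naming the offending coordinates.
        """
        with open(path, newline="") as fh:
            header = next(csv.reader(fh), None)
        if not header or len(header) < 2:
            raise IncidenceError(f"no incidence data in {path}")
        raw_cols = [str(c) for c in header[1:]]
        if len(set(raw_cols)) != len(raw_cols):
            raise IncidenceError(f"duplicated column label in {path}")
        df = pd.read_csv(path, index_col=0, dtype=str)
        if df.empty:
            raise IncidenceError(f"no incidence data in {path}")
        rows = tuple(str(r) for r in df.index)
        cols = tuple(raw_cols)
        if len(set(rows)) != len(rows):
            raise IncidenceError(f"duplicated row label in {path}")
        try:
            arr = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise IncidenceError(f"non-numeric cell in {path}: {exc}") from exc
        bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))
        if bad.size:
            i, j = bad[0]
            raise IncidenceError(
                f"non-binary cell {df.iat[i, j]!r} at (row {rows[i]!r}, col {cols[j]!r})"
            )
        return cls(rows, cols, arr.astype(np.int8))
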