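"""Profile-matrix container, delimited-text I/O, and row standardization.

The data matrix convention throughout the package is *variables in rows,
samples in columns*: column j is the profile of sample unit j over the
n_v measured variables.  All clustering operates on the columns, after each
row has been centered and scaled so that Euclidean distances between
profiles weight every variable equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "read_matrix", "standardize_rows", "write_labels"]


class MatrixValidationError(ValueError):
    """Raised when a profile matrix violates the container invariants."""


@dataclass
class DataMatrix:
    """An n_v x n_s profile matrix with row (variable) and column (sample) ids.

    Parameters
    ----------
    values
        Real matrix, shape (n_v, n_s).
    row_ids
        Unique variable names, length n_v.
    col_ids
        Unique sample names, length n_s.
    standardized
        True once each row has been centered and scaled (see
        :func:`standardize_rows`).
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D matrix")
        n_v, n_s = self.values.shape
        if not self.row_ids:
            self.row_ids = [f"v{i + 1}" for i in range(n_v)]
        if not self.col_ids:
            self.col_ids = [f"s{j + 1}" for j in range(n_s)]
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if n_v < 2 or n_s < 2:
            raise MatrixValidationError(
                f"need at least 2 variables and 2 samples, got {n_v} x {n_s}"
            )
        if len(self.row_ids) != n_v or len(self.col_ids) != n_s:
            raise MatrixValidationError("id lists do not match matrix dimensions")
        if len(set(self.row_ids)) != n_v:
            raise MatrixValidationError("duplicate variable ids")
        if len(set(self.col_ids)) != n_s:
            raise MatrixValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                "missing or non-finite value at variable "
                f"'{self.row_ids[bad[0]]}', sample '{self.col_ids[bad[1]]}'; "
                "impute or remove incomplete profiles before analysis"
            )

    @property
    def n_v(self) -> int:
        return self.values.shape[0]

    @property
    def n_s(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, standardized: bool | None = None) -> "DataMatrix":
        """Copy carrying new values but the same ids."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            standardized=self.standardized if standardized is None else standardized,
        )


def read_matrix(path, delimiter: str = "\t", samples_in: str = "columns") -> DataMatrix:
    """Read a delimited numeric table into a :class:`DataMatrix`.

    The file must have one header row and one id column.  With
    ``samples_in="columns"`` (default) the table is already in the
    variables x samples orientation; with ``samples_in="rows"`` it is
    transposed on read so the returned matrix always has samples in columns.
    """
    if samples_in not in ("columns", "rows"):
        raise ValueError(f"samples_in must be 'columns' or 'rows', got {samples_in!r}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if frame.isna().any().any():
        r, c = next(zip(*np.where(frame.isna().values)))
        raise MatrixValidationError(
            f"missing value at row '{frame.index[r]}', column '{frame.columns[c]}'; "
            "impute before running the analysis"
        )
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if coerced.isna().any():
                row = frame.index[int(np.argmax(coerced.isna().to_numpy()))]
                raise MatrixValidationError(
                    f"non-numeric cell at row '{row}', column '{col}'"
                ) from exc
        raise
    if samples_in == "rows":
        values = values.T
        return DataMatrix(values, row_ids=list(frame.columns), col_ids=list(frame.index))
    return DataMatrix(values, row_ids=list(frame.index), col_ids=list(frame.columns))


def write_matrix(X: DataMatrix, path, delimiter: str = "\t") -> None:
    """Write a :class:`DataMatrix` as a delimited table (samples in columns)."""
    pd.DataFrame(X.values, index=X.row_ids, columns=X.col_ids).to_csv(path, sep=delimiter)


def standardize_rows(
    X: DataMatrix, method: str = "mean_sd", trim_fraction: float = 0.05
) -> DataMatrix:
    """Center and scale each variable (row) of the matrix.

    ``method="mean_sd"`` subtracts the row mean and divides by the sample
    standard deviation (divisor n_s - 1).  ``method="trimmed"`` centers by
    the symmetric trimmed mean and scales by the standard deviation of the
    retained (untrimmed) observations, a robust variant for data with
    outlying profiles.

    Raises
    ------
    MatrixValidationError
        If any row is constant (zero variance) so no scale exists.
    """
    if method not in ("mean_sd", "trimmed"):
        raise ValueError(f"unknown standardization method {method!r}")
    if not (0.0 <= trim_fraction <= 0.25):
        raise ValueError(f"trim_fraction must be in [0, 0.25], got {trim_fraction}")

    V = X.values
    if method == "mean_sd":
        center = V.mean(axis=1, keepdims=True)
        scale = V.std(axis=1, ddof=1, keepdims=True)
    else:
        n_cut = int(np.floor(trim_fraction * X.n_s))
        S = np.sort(V, axis=1)
        kept = S[:, n_cut : X.n_s - n_cut] if n_cut else S
        center = kept.mean(axis=1, keepdims=True)
        scale = kept.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(scale.ravel() == 0.0)
    if zero.size:
        raise MatrixValidationError(
            f"zero variance: variable '{X.row_ids[zero[0]]}' is constant "
            "(after trimming)" if method == "trimmed"
            else f"zero variance: variable '{X.row_ids[zero[0]]}' is constant"
        )
    return X.with_values((V - center) / scale, standardized=True)


def write_labels(result, path, delimiter: str = "\t") -> None:
    """Write per-sample cluster labels as a two-column delimited file.

    Labels are consecutive integers starting at 1, numbered by decreasing
    cluster size (ties broken by first-appearing sample), as produced by the
    detection procedure.
    """
    labels = np.asarray(result.labels)
    ids = list(result.col_ids)
    if labels.size == 0:
        raise ValueError("empty detection result: no labels to write")
    if len(ids) != labels.size:
        raise ValueError("label vector and sample ids differ in length")
    pd.DataFrame({"sample_id": ids, "cluster": labels}).to_csv(
        path, sep=delimiter, index=False
    )
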