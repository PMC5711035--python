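"""Gene-by-timepoint expression matrices and their tabular I/O.

The container mirrors the shape of synchronized cell-cycle time-course
experiments: rows are genes, columns are sampling times in minutes, values
are nonnegative continuous expression levels. A configurable number of
leading time points can be marked as chemically perturbed transients and
excluded from downstream curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "write_expression"]


@dataclass
class ExpressionMatrix:
    """Continuous expression of ``n_genes`` genes at ``n_times`` time points.

    Parameters
    ----------
    gene_ids
        One identifier per row.
    times
        Sampling times in minutes, strictly increasing.
    values
        Array of shape ``(n_genes, n_times)``; nonnegative continuous
        expression, one series per gene.
    transient_skip
        Number of leading time points treated as post-synchronization
        transients and excluded from fitting. Must leave at least 5 points
        (one per free sinusoid parameter) available.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    transient_skip: int = 2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (genes x times) array")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {self.times.size} times"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.transient_skip < 0:
            raise ValueError("transient_skip must be nonnegative")
        if self.transient_skip >= self.times.size - 5:
            raise ValueError(
                "transient_skip leaves fewer than 6 points; cannot fit a "
                "5-parameter decaying sinusoid"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.times)


def read_expression(path: str | Path, transient_skip: int = 2) -> ExpressionMatrix:
    """Read a gene x time table (CSV, TSV or XLSX decided by suffix).

    Contract: header row holds sampling times in minutes, first column holds
    gene identifiers. Raises ``ValueError`` naming the offending cell when a
    value fails to parse as a number.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(path, index_col=0)
    else:
        sep = "\t" if suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, index_col=0, sep=sep)

    try:
        times = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: header row must contain numeric times: {exc}") from None

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row "
                f"{row + 2} (gene {df.index[row]!r}), column {j + 2}"
            )
        if series.isna().any():
            row = int(np.flatnonzero(series.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: missing value at row {row + 2} (gene "
                f"{df.index[row]!r}), column {j + 2}"
            )
        values[:, j] = series.to_numpy()

    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        times=times,
        values=values,
        transient_skip=transient_skip,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the same dialect :func:`read_expression` consumes."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id")
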