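"""Reading and writing count tables, model specs and distributions.

Count inputs are plain CSV/TSV (one integer per row with a header for a
single condition; a genes x cells table with a leading index column for
matrices) or MatrixMarket triplets for sparse matrices.  Values must be
nonnegative and integer-valued; floats within 1e-6 of an integer are
accepted with a warning (normalized inputs), anything else is rejected
with the offending column/row named.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .models import GeneModelSpec

__all__ = ["load_counts", "save_counts", "load_spec", "save_spec",
           "distribution_to_csv"]


def _validate_numeric(values: np.ndarray, what: str) -> np.ndarray:
    if np.any(~np.isfinite(values)):
        bad = int(np.nonzero(~np.isfinite(values.ravel()))[0][0])
        raise ValueError(f"{what}: non-finite value at flat position {bad}")
    if np.any(values < 0):
        bad = int(np.nonzero((values < 0).ravel())[0][0])
        raise ValueError(f"{what}: negative value at flat position {bad}")
    rounded = np.round(values)
    if np.any(np.abs(values - rounded) > 1e-6):
        bad = int(np.nonzero((np.abs(values - rounded) > 1e-6).ravel())[0][0])
        raise ValueError(
            f"{what}: non-integer value at flat position {bad}; "
            "counts must be integers (tolerance 1e-6)")
    if np.any(values != rounded):
        warnings.warn(f"{what}: float counts within 1e-6 of integers were "
                      "rounded (normalized input?)")
    return rounded.astype(np.int64)


def load_counts(path: Union[str, Path], fmt: str = None):
    """Load a count vector or matrix from CSV/TSV/MTX.

    Returns a 1-D integer array for a single-column table, otherwise a
    genes x cells DataFrame (first CSV column taken as the gene index).
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                         dtype=float)
        return pd.DataFrame(_validate_numeric(arr, str(path)))
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unsupported format {fmt!r} (csv, tsv, mtx)")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    for col in df.columns[1:] if df.shape[1] > 1 else df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} is not numeric")
    if df.shape[1] == 1:
        if not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
            raise ValueError(
                f"{path}: column {df.columns[0]!r} is not numeric")
        return _validate_numeric(df.iloc[:, 0].to_numpy(dtype=float),
                                 str(path))
    if not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.set_index(df.columns[0])
    vals = _validate_numeric(df.to_numpy(dtype=float), str(path))
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def save_counts(counts, path: Union[str, Path], name: str = "count") -> None:
    """Write a 1-D count vector (header ``name``) or a matrix to CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    if isinstance(counts, pd.DataFrame):
        counts.to_csv(path, sep=sep)
    else:
        pd.DataFrame({name: np.asarray(counts)}).to_csv(path, sep=sep,
                                                        index=False)


def save_spec(spec: GeneModelSpec, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(spec.as_dict(), indent=1) + "\n")


def load_spec(path: Union[str, Path]) -> GeneModelSpec:
    return GeneModelSpec.from_dict(json.loads(Path(path).read_text()))


def distribution_to_csv(marginal: np.ndarray, path: Union[str, Path]) -> None:
    """Export a marginal mRNA distribution as a two-column (m, probability) CSV."""
    marg = np.asarray(marginal, dtype=float)
    pd.DataFrame({"m": np.arange(marg.size), "probability": marg}) \
        .to_csv(path, index=False)
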