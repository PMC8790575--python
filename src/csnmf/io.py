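"""Matrix file I/O and run manifests.

Supported formats: MatrixMarket (``.mtx``, coordinate for matrices with
fewer than 50% non-zeros, array otherwise) and delimited text
(``.tsv``/``.csv``).  Reading rejects negative entries with a
diagnostic naming the first offending coordinate.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["read_matrix", "write_matrix", "write_manifest", "read_manifest"]

_SEPS = {"tsv": "\t", "csv": ","}


def _infer_format(path, fmt):
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("mtx", "tsv", "csv"):
        return suffix
    raise ValueError(
        f"cannot infer format from {path!r}; pass format='mtx'|'tsv'|'csv'"
    )


def read_matrix(path, format=None):
    """Read a non-negative dense matrix from mtx/tsv/csv."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        X = scipy.io.mmread(path)
        if scipy.sparse.issparse(X):
            X = X.toarray()
        X = np.asarray(X, dtype=float)
    else:
        frame = pd.read_csv(path, header=None, sep=_SEPS[fmt])
        X = frame.to_numpy(dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.isfinite(X).all():
        i, j = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"{path}: non-finite entry at row {i}, column {j}")
    if (X < 0).any():
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(
            f"{path}: negative entry {X[i, j]} at row {i}, column {j}"
        )
    return X


def write_matrix(matrix, path, format=None):
    """Write a matrix to mtx/tsv/csv at full double precision."""
    X = np.asarray(matrix, dtype=float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        density = np.count_nonzero(X) / max(1, X.size)
        if density < 0.5:
            scipy.io.mmwrite(path, scipy.sparse.coo_matrix(X))
        else:
            scipy.io.mmwrite(path, X)
    else:
        np.savetxt(path, np.atleast_2d(X), fmt="%.10g", delimiter=_SEPS[fmt])


def write_manifest(path, payload):
    """Write a machine-readable JSON manifest next to run outputs."""
    from . import __version__

    record = {"csnmf_version": __version__}
    record.update(payload)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")


def read_manifest(path):
    return json.loads(Path(path).read_text())
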