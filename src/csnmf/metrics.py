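"""Evaluation metrics for factorization quality.

Reconstruction SNR, residual RMSE, and the basis distance between an
estimated and a reference basis matrix.  Because any NMF is invariant
to a simultaneous column/row permutation of (W, H), the basis distance
aligns columns first by default, using an exact optimal assignment
under squared-Euclidean column distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "snr",
    "rmse",
    "match_columns",
    "basis_distance",
    "stabilization_iteration",
    "EvalReport",
    "evaluate",
]


def _residual_norms(X, W, H):
    X = np.asarray(X, dtype=float)
    norm_x = np.linalg.norm(X)
    if norm_x == 0.0:
        raise ValueError("X is all-zero; metric undefined")
    return norm_x, float(np.linalg.norm(X - np.asarray(W) @ np.asarray(H)))


def snr(X, W, H):
    """Reconstruction signal-to-noise ratio, dB.

    ``10 log10(||X||_F^2 / ||X - WH||_F^2)``; a zero residual is
    reported as ``inf``.
    """
    norm_x, res = _residual_norms(X, W, H)
    if res == 0.0:
        return float("inf")
    return float(10.0 * np.log10(norm_x**2 / res**2))


def rmse(X, W, H):
    """Residual Frobenius norm ||X - WH||_F (no normalizing divisor)."""
    return _residual_norms(X, W, H)[1]


def match_columns(W_est, W_true):
    """Column permutation of W_est best matching W_true.

    Solves the optimal assignment under squared-Euclidean column
    distances exactly; returns ``perm`` such that ``W_est[:, perm]``
    aligns column j of the estimate with column j of the reference.
    """
    A = np.asarray(W_est, dtype=float)
    B = np.asarray(W_true, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    # cost[i, j] = ||A[:, i] - B[:, j]||^2
    cost = (
        np.einsum("ki,ki->i", A, A)[:, None]
        + np.einsum("kj,kj->j", B, B)[None, :]
        - 2.0 * A.T @ B
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(A.shape[1], dtype=np.intp)
    perm[cols] = rows
    return perm


def basis_distance(W_est, W_true, align=True, rescale=False):
    """Frobenius distance ||W_est - W_true||_F, optionally after alignment.

    ``align=True`` (default) permutes the estimated columns by
    :func:`match_columns` first; ``rescale=True`` additionally
    L2-normalizes the non-zero columns of both matrices before matching
    and measuring, removing the column-scale ambiguity.
    """
    A = np.asarray(W_est, dtype=float)
    B = np.asarray(W_true, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if rescale:
        def unit(M):
            norms = np.linalg.norm(M, axis=0)
            return M / np.where(norms > 0, norms, 1.0)
        A, B = unit(A), unit(B)
    if align:
        A = A[:, match_columns(A, B)]
    return float(np.linalg.norm(A - B))


def stabilization_iteration(trajectory, window=5, rtol=1e-3):
    """First iteration after which a trajectory is stable.

    Returns the smallest (1-based) iteration index t such that the next
    ``window`` successive absolute changes are all below
    ``rtol * trajectory[-1]``; if the trajectory never stabilizes the
    last iteration index is returned.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.size < 2:
        return int(traj.size)
    diffs = np.abs(np.diff(traj))
    thresh = rtol * abs(traj[-1])
    if thresh == 0.0:
        thresh = rtol * max(traj.max(), np.finfo(float).tiny)
    for t in range(diffs.size - window + 1):
        if (diffs[t : t + window] < thresh).all():
            return t + 1
    return int(traj.size)


@dataclass
class EvalReport:
    """Bundle of reconstruction metrics for one fitted factor pair."""

    snr_db: float
    rmse: float
    relative_error: float
    basis_distance: float | None = None
    permutation: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self):
        out = {
            "snr_db": self.snr_db,
            "rmse": self.rmse,
            "relative_error": self.relative_error,
        }
        if self.basis_distance is not None:
            out["basis_distance"] = self.basis_distance
        return out


def evaluate(X, W, H, W_true=None, align=True):
    """Compute the standard metric bundle, with basis distance when a
    reference basis is supplied."""
    norm_x, res = _residual_norms(X, W, H)
    report = EvalReport(
        snr_db=snr(X, W, H),
        rmse=res,
        relative_error=res / norm_x,
    )
    if W_true is not None:
        report.permutation = match_columns(W, W_true)
        report.basis_distance = basis_distance(W, W_true, align=align)
    return report
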