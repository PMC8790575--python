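"""Non-negative least-squares engines.

Everything in this module solves variants of

    min_h ||b - A h||_2   subject to  h >= 0,

possibly for many right-hand sides at once and possibly with a fixed
support (a set of coordinates pinned to zero).  The multi-column solver
is a fast combinatorial NNLS (FC-NNLS): it works on the normal
equations, groups right-hand-side columns that share a passive
(allowed-positive) set, and solves each group's linear system in one
batched call.  A brute-force best-subset oracle is also provided; it is
exponential in the budget and intended for tests only.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import nnls as _lawson_hanson

__all__ = [
    "nnls_single",
    "fcnnls",
    "restricted_nnls",
    "best_subset_nnls_oracle",
    "best_subset_matrix_oracle",
]

#: tolerance on the maximum dual (gradient) value in the KKT check of the
#: active-set iteration; standard Lawson-Hanson practice, far below the
#: scale of any data handled here.
DUAL_TOL = 1e-10


def nnls_single(design, target):
    """Solve ``min ||target - design @ h||`` s.t. ``h >= 0`` for one column.

    Thin wrapper around the Lawson-Hanson active-set solver.
    """
    A = np.asarray(design, dtype=float)
    b = np.asarray(target, dtype=float).ravel()
    if A.ndim != 2 or A.size == 0:
        raise ValueError("design matrix must be a non-empty 2-D array")
    if A.shape[0] != b.size:
        raise ValueError(
            f"design has {A.shape[0]} rows but target has {b.size} entries"
        )
    h, _ = _lawson_hanson(A, b)
    return h


def _solve_full(CtC, CtB):
    """Solve the normal equations, falling back to least-norm if singular."""
    try:
        sol = np.linalg.solve(CtC, CtB)
        if not np.isfinite(sol).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "rank-deficient normal equations; using a least-norm solve",
            RuntimeWarning,
            stacklevel=3,
        )
        sol = np.linalg.lstsq(CtC, CtB, rcond=None)[0]
    return sol


def _cssls(CtC, CtB, passive=None):
    """Combinatorial subspace least squares.

    Solves the normal equations ``CtC x = CtB`` column by column with each
    column restricted to its passive set (entries outside are zero).
    Columns are batched by passive-set size so the triangular solves run
    as one stacked ``numpy.linalg.solve`` call per size.
    """
    if passive is None:
        return _solve_full(CtC, CtB)
    q, r = CtB.shape
    X = np.zeros((q, r))
    counts = passive.sum(axis=0)
    for k in np.unique(counts):
        if k == 0:
            continue
        cols = np.flatnonzero(counts == k)
        if k == q:
            X[:, cols] = _solve_full(CtC, CtB[:, cols])
            continue
        idx = np.empty((cols.size, k), dtype=np.intp)
        for t, c in enumerate(cols):
            idx[t] = np.flatnonzero(passive[:, c])
        subs = CtC[idx[:, :, None], idx[:, None, :]]
        rhs = CtB[idx, cols[:, None]]
        try:
            sol = np.linalg.solve(subs, rhs[..., None])[..., 0]
            if not np.isfinite(sol).all():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(
                "rank-deficient passive block; using a least-norm solve",
                RuntimeWarning,
                stacklevel=3,
            )
            sol = np.empty_like(rhs)
            for t in range(cols.size):
                sol[t] = np.linalg.lstsq(subs[t], rhs[t], rcond=None)[0]
        X[idx, cols[:, None]] = sol
    return X


def _fcnnls_core(CtC, CtB, allowed):
    """FC-NNLS active-set iteration on precomputed normal equations.

    ``allowed`` is a boolean (q, r) array: entries outside it are pinned
    to zero (used by :func:`restricted_nnls`); the passive sets explored
    by the iteration are always subsets of ``allowed``.
    """
    q, r = CtB.shape
    K = _cssls(CtC, CtB, allowed if not allowed.all() else None)
    P = (K > 0) & allowed
    Fset = np.flatnonzero((K < 0).any(axis=0))
    K[~P] = 0.0
    Dwork = K.copy()
    Wdual = np.zeros_like(K)
    dual_tol = DUAL_TOL * max(1.0, float(np.abs(CtB).max(initial=0.0)))
    outer = 0
    while Fset.size:
        outer += 1
        if outer > 20 * q + 50:
            warnings.warn(
                "FC-NNLS active-set iteration did not converge; "
                "returning the current (clamped) iterate",
                RuntimeWarning,
                stacklevel=3,
            )
            K[:, Fset] = np.maximum(K[:, Fset], 0.0)
            break
        K[:, Fset] = _cssls(CtC, CtB[:, Fset], P[:, Fset])
        Hset = Fset[(K[:, Fset] < 0).any(axis=0)]
        inner = 0
        while Hset.size:
            inner += 1
            if inner > 3 * q + 10:
                warnings.warn(
                    "FC-NNLS feasibility backtracking stalled; clamping",
                    RuntimeWarning,
                    stacklevel=3,
                )
                K[:, Hset] = np.maximum(K[:, Hset], 0.0)
                break
            negm = P[:, Hset] & (K[:, Hset] < 0)
            alpha = np.full((q, Hset.size), np.inf)
            i, j = np.nonzero(negm)
            dvals = Dwork[i, Hset[j]]
            alpha[i, j] = dvals / (dvals - K[i, Hset[j]])
            imin = alpha.argmin(axis=0)
            amin = alpha[imin, np.arange(Hset.size)]
            Dwork[:, Hset] -= amin[None, :] * (Dwork[:, Hset] - K[:, Hset])
            Dwork[imin, Hset] = 0.0
            P[imin, Hset] = False
            K[:, Hset] = _cssls(CtC, CtB[:, Hset], P[:, Hset])
            Hset = Hset[(K[:, Hset] < 0).any(axis=0)]
        Wdual[:, Fset] = CtB[:, Fset] - CtC @ K[:, Fset]
        cand = (~P[:, Fset]) & allowed[:, Fset]
        dualvals = np.where(cand, Wdual[:, Fset], -np.inf)
        not_opt = (dualvals > dual_tol).any(axis=0)
        Fnew = Fset[not_opt]
        if Fnew.size:
            sub = np.where((~P[:, Fnew]) & allowed[:, Fnew], Wdual[:, Fnew], -np.inf)
            imax = sub.argmax(axis=0)
            P[imax, Fnew] = True
            Dwork[:, Fnew] = K[:, Fnew]
        Fset = Fnew
    return K


def _prepare(design, targets):
    A = np.asarray(design, dtype=float)
    B = np.asarray(targets, dtype=float)
    one_d = B.ndim == 1
    if one_d:
        B = B[:, None]
    if A.ndim != 2 or A.size == 0:
        raise ValueError("design matrix must be a non-empty 2-D array")
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"design has {A.shape[0]} rows but targets have {B.shape[0]}"
        )
    return A, B, one_d


def fcnnls(design, targets):
    """Fast combinatorial NNLS for multiple right-hand sides.

    Returns the (q, r) matrix of column-wise non-negative least-squares
    solutions of ``min ||targets - design @ X||_F`` s.t. ``X >= 0``,
    numerically identical to calling :func:`nnls_single` per column.
    All-zero design columns get a zero coefficient.
    """
    A, B, one_d = _prepare(design, targets)
    CtC = A.T @ A
    CtB = A.T @ B
    allowed = np.broadcast_to(
        (np.diag(CtC) > 0.0)[:, None], CtB.shape
    ).copy()
    K = _fcnnls_core(CtC, CtB, allowed)
    return K[:, 0] if one_d else K


def restricted_nnls(design, targets, support_masks):
    """Column-wise NNLS with per-column supports fixed in advance.

    ``support_masks`` is a boolean (q, r) array; entries that are False
    are returned as exact zeros, entries that are True solve the reduced
    NNLS problem on the corresponding sub-design.  All columns are
    batched through one masked FC-NNLS pass (columns sharing a mask
    share its solve path).  An all-zero design column inside a support
    gets coefficient 0 with a warning.
    """
    A, B, one_d = _prepare(design, targets)
    masks = np.asarray(support_masks, dtype=bool)
    if one_d and masks.ndim == 1:
        masks = masks[:, None]
    if masks.shape != (A.shape[1], B.shape[1]):
        raise ValueError(
            f"support masks shaped {masks.shape}, expected "
            f"{(A.shape[1], B.shape[1])}"
        )
    CtC = A.T @ A
    CtB = A.T @ B
    usable = np.diag(CtC) > 0.0
    allowed = masks & usable[:, None]
    if (masks & ~usable[:, None]).any():
        warnings.warn(
            "active set contains an all-zero design column; "
            "its coefficient is set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    K = _fcnnls_core(CtC, CtB, allowed)
    K[~masks] = 0.0
    return K[:, 0] if one_d else K


def best_subset_nnls_oracle(design, target, budget):
    """Exhaustive best-subset NNLS for one right-hand side (test oracle).

    Enumerates every support of size <= ``budget``, solves the NNLS
    problem restricted to each, and returns ``(h, objective)`` where the
    objective is the squared residual norm of the global minimizer.
    Exponential in ``budget``; guarded to small problems.
    """
    A, B, _ = _prepare(design, target)
    b = B[:, 0]
    q = A.shape[1]
    budget = int(budget)
    if budget < 0:
        raise ValueError("budget must be >= 0")
    budget = min(budget, q)
    if comb(q, budget) > 10_000:
        raise ValueError("combinatorial size guard exceeded (choose(q, budget) > 1e4)")
    best_h = np.zeros(q)
    best_obj = float(b @ b)
    for size in range(1, budget + 1):
        for support in combinations(range(q), size):
            cols = list(support)
            h_sub = nnls_single(A[:, cols], b)
            resid = b - A[:, cols] @ h_sub
            obj = float(resid @ resid)
            if obj < best_obj - 1e-15 * max(1.0, best_obj):
                best_obj = obj
                best_h = np.zeros(q)
                best_h[cols] = h_sub
    return best_h, best_obj


def best_subset_matrix_oracle(design, targets, budget):
    """Exhaustive best-subset NNLS with a *global* budget over a matrix.

    Enumerates every support of size <= ``budget`` over the whole (q, r)
    coefficient grid, solves each column's reduced NNLS, and returns
    ``(H, objective)`` with the squared Frobenius residual of the global
    minimizer.  Test oracle only: cost grows as choose(q*r, budget).
    """
    A, B, _ = _prepare(design, targets)
    q = A.shape[1]
    r = B.shape[1]
    budget = int(budget)
    if budget < 0:
        raise ValueError("budget must be >= 0")
    budget = min(budget, q * r)
    if comb(q * r, budget) > 100_000:
        raise ValueError("combinatorial size guard exceeded")
    col_sq = np.einsum("ij,ij->j", B, B)
    base_obj = float(col_sq.sum())

    cache: dict[tuple[int, tuple[int, ...]], tuple[np.ndarray, float]] = {}

    def column_fit(col, rows):
        key = (col, rows)
        if key not in cache:
            cols = list(rows)
            h_sub = nnls_single(A[:, cols], B[:, col])
            resid = B[:, col] - A[:, cols] @ h_sub
            cache[key] = (h_sub, float(resid @ resid))
        return cache[key]

    best_H = np.zeros((q, r))
    best_obj = base_obj
    for size in range(1, budget + 1):
        for support in combinations(range(q * r), size):
            per_col: dict[int, list[int]] = {}
            for flat in support:
                per_col.setdefault(flat % r, []).append(flat // r)
            obj = base_obj
            for col, rows in per_col.items():
                _, col_obj = column_fit(col, tuple(rows))
                obj += col_obj - col_sq[col]
            if obj < best_obj - 1e-15 * max(1.0, best_obj):
                best_obj = obj
                best_H = np.zeros((q, r))
                for col, rows in per_col.items():
                    h_sub, _ = column_fit(col, tuple(rows))
                    best_H[list(rows), col] = h_sub
    return best_H, best_obj
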