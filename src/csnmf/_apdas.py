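"""Alternating primal-dual active-set (APDAS) machinery.

The co-sparse NMF problem

    min ||X - W H||_F^2   s.t.  W, H >= 0,  nnz(H) <= budget_H,
                                            nnz(W) <= budget_W

is solved by alternating a primal-dual active-set (PDAS) pass between
the two factors.  One pass on a factor consists of: coordinate-wise
unconstrained optima, a "sacrifice" score per entry (the loss increase
incurred by pinning that entry to zero, clamped to zero for negative
candidates so non-negativity is respected), selection of the
budget-many largest sacrifices as the active set, and a support-
restricted NNLS refit.  The W pass is the H pass applied to the
transposed problem ``X^T ~ H^T W^T``.
"""

from __future__ import annotations

import numpy as np

from .nnls import fcnnls, restricted_nnls

__all__ = [
    "coordinate_optimum",
    "sacrifice",
    "select_active",
    "update_h",
    "update_w",
    "normalize_columns",
    "relative_error",
    "init_factors",
    "recalibrate",
    "sparse_nnls",
    "apdas",
]


def coordinate_optimum(X, design, coef):
    """Coordinate-wise minimizers of the partial quadratic loss.

    For each entry (p, t) of ``coef``, returns the unconstrained scalar
    minimizer of ``||X - design @ C||_F^2`` over ``C[p, t]`` with every
    other entry fixed; in closed form

        coef + design^T (X - design @ coef) / ||design[:, p]||^2.

    Entries belonging to an all-zero design column (dead atom) are
    reported as 0.  Also returns the squared column norms of the design.
    """
    X = np.asarray(X, dtype=float)
    design = np.asarray(design, dtype=float)
    coef = np.asarray(coef, dtype=float)
    if design.shape[0] != X.shape[0] or design.shape[1] != coef.shape[0] \
            or coef.shape[1] != X.shape[1]:
        raise ValueError(
            f"non-conforming shapes: X {X.shape}, design {design.shape}, "
            f"coef {coef.shape}"
        )
    norms = np.einsum("ij,ij->j", design, design)
    grad = design.T @ (X - design @ coef)
    with np.errstate(divide="ignore", invalid="ignore"):
        cand = coef + grad / norms[:, None]
    cand[norms == 0.0, :] = 0.0
    return cand, norms


def sacrifice(col_norms, candidate):
    """Loss increase from pinning each coordinate optimum to zero.

    ``delta[p, t] = col_norms[p] * candidate[p, t]**2`` when the
    candidate is non-negative, else 0 (a negative candidate would be
    clipped by the non-negativity constraint anyway, so zeroing it
    sacrifices nothing).
    """
    norms = np.asarray(col_norms, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if (norms < 0).any():
        raise ValueError("squared column norms must be non-negative")
    delta = norms[:, None] * np.square(cand)
    delta[cand < 0] = 0.0
    return delta


def select_active(delta, budget):
    """Boolean mask of the ``budget`` largest positive sacrifices.

    Ties at the threshold are broken by stable row-major index order;
    zero-sacrifice entries are never activated, so the selected set may
    be smaller than the budget.
    """
    delta = np.asarray(delta, dtype=float)
    budget = int(budget)
    if budget < 1:
        raise ValueError("budget must be a positive integer")
    flat = delta.ravel()
    order = np.argsort(-flat, kind="stable")[:budget]
    order = order[flat[order] > 0.0]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order] = True
    return mask.reshape(delta.shape)


def update_h(X, W, active_mask):
    """Support-restricted NNLS refit of the coding matrix.

    Entries of H outside ``active_mask`` (K x N boolean) are exact
    zeros; active entries solve each column's reduced NNLS problem.
    """
    return restricted_nnls(W, X, active_mask)


def update_w(X, H, active_mask):
    """Row-wise mirror of :func:`update_h` on the transposed problem."""
    active_mask = np.asarray(active_mask, dtype=bool)
    return restricted_nnls(H.T, np.asarray(X, dtype=float).T, active_mask.T).T


def normalize_columns(W, norm="l1"):
    """Normalize the columns of W, returning the scales used.

    ``norm='l1'`` divides each column by its entry sum (the update rule
    of the solver loop); ``'l2'`` by its Euclidean length.  All-zero
    columns are left unchanged with scale 1.
    """
    W = np.asarray(W, dtype=float)
    if norm == "l1":
        scales = W.sum(axis=0)
    elif norm == "l2":
        scales = np.linalg.norm(W, axis=0)
    else:
        raise ValueError(f"unknown norm {norm!r}; use 'l1' or 'l2'")
    scales = np.where(scales > 0.0, scales, 1.0)
    return W / scales, scales


def relative_error(X, W, H):
    """Relative Frobenius reconstruction error ||X - WH||_F / ||X||_F."""
    X = np.asarray(X, dtype=float)
    norm_x = np.linalg.norm(X)
    if norm_x == 0.0:
        raise ValueError("X is all-zero; relative error undefined")
    return float(np.linalg.norm(X - W @ H) / norm_x)


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _nndsvd(X, k, eps):
    """Split-sign SVD initialization (NNDSVD-style).

    Rank-k SVD of X with, for each non-leading pair, the larger of the
    positive/negative split retained; zeros are replaced by ``eps``.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if k > np.count_nonzero(S > 1e-12 * S[0] if S.size else 0):
        raise ValueError(
            f"svd initialization needs {k} non-trivial singular triplets; "
            f"X has {np.count_nonzero(S > 0)}"
        )
    D, N = X.shape
    W = np.zeros((D, k))
    H = np.zeros((k, N))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0.0), np.maximum(-u, 0.0)
        vp, vn = np.maximum(v, 0.0), np.maximum(-v, 0.0)
        mp = np.linalg.norm(up) * np.linalg.norm(vp)
        mn = np.linalg.norm(un) * np.linalg.norm(vn)
        if mp >= mn:
            uu, vv, sig = up, vp, mp
        else:
            uu, vv, sig = un, vn, mn
        if sig > 0:
            nu = np.linalg.norm(uu)
            nv = np.linalg.norm(vv)
            W[:, j] = np.sqrt(S[j] * sig) * uu / nu
            H[j, :] = np.sqrt(S[j] * sig) * vv / nv
    W[W <= 0.0] = eps
    H[H <= 0.0] = eps
    return W, H


def init_factors(X, k, strategy="uniform", seed=None):
    """Initial non-negative factor pair (W0, H0).

    strategies:
      - ``uniform``: i.i.d. U(0, 1) entries;
      - ``subsample``: entries drawn with replacement from the entries
        of X;
      - ``svd``: split-sign rank-k SVD with zeros replaced by a small
        positive constant.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    k = int(k)
    if k < 1:
        raise ValueError("K must be a positive integer")
    D, N = X.shape
    rng = _as_rng(seed)
    if strategy == "uniform":
        return rng.uniform(size=(D, k)), rng.uniform(size=(k, N))
    if strategy == "subsample":
        pool = X.ravel()
        W = rng.choice(pool, size=(D, k), replace=True)
        H = rng.choice(pool, size=(k, N), replace=True)
        return W, H
    if strategy == "svd":
        if not (X > 0).any():
            raise ValueError("svd initialization undefined for an all-zero X")
        eps = float(X[X > 0].mean()) * 1e-2
        return _nndsvd(X, k, eps)
    raise ValueError(f"unknown initialization {strategy!r}")


def recalibrate(X, W, H):
    """FC-NNLS re-calibration: refit H unrestrictedly on the current W.

    Returns ``(W, H_new)`` with ``H_new`` the multi-column NNLS fit of X
    on W; W is unchanged.  Applied once before the main loop when
    requested.
    """
    return W, fcnnls(W, np.asarray(X, dtype=float))


def _pdas_pass(X, design, coef, budget):
    """One PDAS pass on one factor: candidates, sacrifices, active set,
    restricted refit.  Returns the new factor and its active mask."""
    cand, norms = coordinate_optimum(X, design, coef)
    delta = sacrifice(norms, cand)
    mask = select_active(delta, budget)
    new = restricted_nnls(design, X, mask)
    return new, mask


def sparse_nnls(design, targets, budget, max_sweeps=30, warm_start=True):
    """Budgeted sparse non-negative coding with a fixed design.

    Iterates PDAS passes (coordinate optima -> sacrifices -> active set
    -> restricted NNLS) on the coding matrix until the active set stops
    changing.  This is the single-factor sub-problem the alternating
    solver applies once per outer iteration; iterated to a fixed point
    it is the PDAS method for the globally budgeted non-negative
    best-subset problem.
    """
    design = np.asarray(design, dtype=float)
    B = np.asarray(targets, dtype=float)
    one_d = B.ndim == 1
    if one_d:
        B = B[:, None]
    q, r = design.shape[1], B.shape[1]
    H = fcnnls(design, B) if warm_start else np.zeros((q, r))
    prev_mask = None
    for _ in range(max_sweeps):
        H, mask = _pdas_pass(B, design, H, budget)
        if prev_mask is not None and np.array_equal(mask, prev_mask):
            break
        prev_mask = mask
    return (H[:, 0], mask[:, 0]) if one_d else (H, mask)


def apdas(
    X,
    k,
    budget_h,
    budget_w,
    *,
    alpha=1.0,
    beta=1.0,
    max_iter=200,
    tol=1e-4,
    init="uniform",
    seed=None,
    recalibrate_first=True,
    norm="l1",
    normalize_last=False,
    compensate_h=True,
    reinit_dead_atoms=False,
):
    """Full alternating primal-dual active-set loop.

    Per iteration each factor gets either a PDAS pass (sparsity level
    < 1) or a plain multi-column NNLS refit (level = 1), in H-first
    order when ``alpha <= beta`` and W-first otherwise.  W columns are
    normalized each iteration; with H-first order the final iteration's
    normalization is skipped (unless ``normalize_last``) so the returned
    pair reproduces X.  Stops when the relative Frobenius error drops to
    ``tol`` or after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    rng = _as_rng(seed)
    W, H = init_factors(X, k, init, rng)
    if recalibrate_first:
        W, H = recalibrate(X, W, H)

    h_first = alpha <= beta
    traj = []
    mask_h = None
    mask_w = None
    converged = False

    def step_h(W, H):
        if alpha < 1.0:
            return _pdas_pass(X, W, H, budget_h)
        H = fcnnls(W, X)
        return H, H > 0.0

    def step_w(W, H):
        if beta < 1.0:
            Wt, mask_t = _pdas_pass(X.T, H.T, W.T, budget_w)
            return Wt.T, mask_t.T
        Wt = fcnnls(H.T, X.T)
        return Wt.T, Wt.T > 0.0

    def revive(W):
        dead = ~(W > 0.0).any(axis=0)
        if dead.any():
            W = W.copy()
            W[:, dead] = rng.uniform(size=(W.shape[0], int(dead.sum())))
        return W

    iterations = 0
    for m in range(1, max_iter + 1):
        iterations = m
        if h_first:
            H, mask_h = step_h(W, H)
            W, mask_w = step_w(W, H)
            if reinit_dead_atoms:
                W = revive(W)
            rel = relative_error(X, W, H)
            traj.append(rel)
            last = rel <= tol or m == max_iter
            if not last or normalize_last:
                W, scales = normalize_columns(W, norm)
                if compensate_h:
                    H = H * scales[:, None]
            if rel <= tol:
                converged = True
                break
        else:
            W, mask_w = step_w(W, H)
            if reinit_dead_atoms:
                W = revive(W)
            W, scales = normalize_columns(W, norm)
            if compensate_h:
                H = H * scales[:, None]
            H, mask_h = step_h(W, H)
            rel = relative_error(X, W, H)
            traj.append(rel)
            if rel <= tol:
                converged = True
                break

    # a dead-atom revival on the very last iteration may leave W over
    # budget; restrict to the last active set in that case
    if beta < 1.0 and mask_w is not None and np.count_nonzero(W) > budget_w:
        W = np.where(mask_w, W, 0.0)

    return {
        "W": W,
        "H": H,
        "trajectory": np.asarray(traj),
        "iterations": iterations,
        "converged": converged,
        "mask_h": mask_h,
        "mask_w": mask_w,
    }
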