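"""Co-sparse NMF model and results objects.

The public surface follows the fitted-model convention: build a
:class:`CSNMF` model from a non-negative data matrix, call
:meth:`CSNMF.fit`, and work with the returned :class:`CSNMFResults`
(factors, error trajectory, diagnostics, ``summary()``).
"""

from __future__ import annotations

import math

import numpy as np

from . import _apdas, metrics

__all__ = ["CSNMF", "CSNMFResults", "element_budget"]


def element_budget(level, n_elements):
    """Integer non-zero budget induced by a sparsity level.

    ``floor(level * n_elements)`` clamped to at least 1; a level of 1
    means the constraint is inactive (budget = number of elements).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"sparsity level must be in [0, 1], got {level}")
    if level == 1.0:
        return int(n_elements)
    return max(1, math.floor(level * n_elements))


def _validate_data(X):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one element")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    if (X < 0).any():
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(f"X must be non-negative; X[{i}, {j}] = {X[i, j]}")
    if not (X > 0).any():
        raise ValueError("X must contain at least one positive entry")
    return X


class CSNMF:
    """Co-sparse non-negative matrix factorization model, X ~ W H.

    Parameters
    ----------
    X : array-like, shape (D, N)
        Non-negative data matrix.
    k : int
        Inner dimension (number of basis columns / atoms).
    alpha : float in [0, 1]
        Sparsity level of the coding matrix H: at most
        ``floor(alpha * k * N)`` non-zeros.  ``alpha = 1`` disables the
        constraint.
    beta : float in [0, 1]
        Sparsity level of the basis matrix W: at most
        ``floor(beta * D * k)`` non-zeros.  ``beta = 1`` disables it.

    With ``alpha = beta = 1`` the model reduces to classical NMF solved
    by alternating (FC-)NNLS.
    """

    def __init__(self, X, k, alpha=1.0, beta=1.0):
        self.X = _validate_data(X)
        self.k = int(k)
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        self.alpha = float(alpha)
        self.beta = float(beta)
        D, N = self.X.shape
        self.budget_h = element_budget(self.alpha, self.k * N)
        self.budget_w = element_budget(self.beta, D * self.k)

    @classmethod
    def from_dataframe(cls, frame, k, alpha=1.0, beta=1.0):
        """Build the model from a pandas DataFrame of intensities."""
        return cls(frame.to_numpy(dtype=float), k, alpha=alpha, beta=beta)

    @property
    def shape(self):
        return self.X.shape

    def fit(
        self,
        *,
        max_iter=200,
        tol=1e-4,
        init="uniform",
        seed=None,
        recalibrate=True,
        norm="l1",
        normalize_last=False,
        compensate_h=True,
        reinit_dead_atoms=False,
    ):
        """Run the alternating primal-dual active-set solver.

        Parameters
        ----------
        max_iter : int
            Iteration cap (each iteration updates both factors).
        tol : float
            Stop when ``||X - WH||_F / ||X||_F <= tol``.
        init : {'uniform', 'subsample', 'svd'}
            Initialization strategy for (W0, H0).
        seed : int or numpy Generator, optional
            Governs all randomness of the fit (initialization, dead-atom
            revival).
        recalibrate : bool
            Refit H by unrestricted FC-NNLS once before the main loop.
        norm : {'l1', 'l2'}
            Column normalization applied to W each iteration.
        normalize_last : bool
            Also normalize W on the final iteration when the update
            order is H-then-W (default off, so the returned pair
            reproduces X without a compensating rescale of H).
        compensate_h : bool
            Apply the inverse column scales to the rows of H after each
            normalization so the product WH is preserved mid-iteration
            (default on: the support selection of the next sparse pass
            is computed from the current iterate, so an uncompensated
            rescale of W corrupts it and the error trajectory need not
            settle).
        reinit_dead_atoms : bool
            Redraw all-zero columns of W from U(0, 1) after each W
            update (default off: a dead atom stays dead, matching the
            literal update rules).

        Returns
        -------
        CSNMFResults
        """
        out = _apdas.apdas(
            self.X,
            self.k,
            self.budget_h,
            self.budget_w,
            alpha=self.alpha,
            beta=self.beta,
            max_iter=max_iter,
            tol=tol,
            init=init,
            seed=seed,
            recalibrate_first=recalibrate,
            norm=norm,
            normalize_last=normalize_last,
            compensate_h=compensate_h,
            reinit_dead_atoms=reinit_dead_atoms,
        )
        config = {
            "max_iter": int(max_iter),
            "tol": float(tol),
            "init": init,
            "seed": seed if seed is None or isinstance(seed, int) else "generator",
            "recalibrate": bool(recalibrate),
            "norm": norm,
            "normalize_last": bool(normalize_last),
            "compensate_h": bool(compensate_h),
            "reinit_dead_atoms": bool(reinit_dead_atoms),
        }
        return CSNMFResults(self, out, config)


class CSNMFResults:
    """Fitted co-sparse NMF factors and diagnostics."""

    def __init__(self, model, solver_output, config):
        self.model = model
        self.W = solver_output["W"]
        self.H = solver_output["H"]
        self.rel_error_trajectory = solver_output["trajectory"]
        self.iterations_used = solver_output["iterations"]
        self.converged = solver_output["converged"]
        self._mask_h = solver_output["mask_h"]
        self._mask_w = solver_output["mask_w"]
        self.config = config

    # -- factor diagnostics -------------------------------------------------

    @property
    def active_H(self):
        """(row, col) index pairs allowed non-zero in the final H update."""
        return np.argwhere(self._mask_h)

    @property
    def active_W(self):
        """(row, col) index pairs allowed non-zero in the final W update."""
        return np.argwhere(self._mask_w)

    @property
    def nnz_H(self):
        return int(np.count_nonzero(self.H))

    @property
    def nnz_W(self):
        return int(np.count_nonzero(self.W))

    @property
    def relative_error(self):
        return float(self.rel_error_trajectory[-1])

    def reconstruction(self):
        """The fitted matrix W @ H."""
        return self.W @ self.H

    @property
    def rmse(self):
        """Frobenius norm of the residual X - W H."""
        return metrics.rmse(self.model.X, self.W, self.H)

    @property
    def snr(self):
        """Reconstruction signal-to-noise ratio in dB."""
        return metrics.snr(self.model.X, self.W, self.H)

    def basis_distance(self, W_true, align=True):
        """Frobenius distance of W to a reference basis (aligned by default)."""
        return metrics.basis_distance(self.W, W_true, align=align)

    def summary(self):
        """Plain-text summary table of the fit."""
        model = self.model
        D, N = model.shape
        lines = [
            "          Co-sparse NMF (APDAS)          ",
            "=" * 41,
            f"{'Data shape':<24}{D} x {N}",
            f"{'Rank K':<24}{model.k}",
            f"{'alpha (H level)':<24}{model.alpha:g}",
            f"{'beta (W level)':<24}{model.beta:g}",
            f"{'nnz(H) / budget':<24}{self.nnz_H} / {model.budget_h}",
            f"{'nnz(W) / budget':<24}{self.nnz_W} / {model.budget_w}",
            "-" * 41,
            f"{'Iterations':<24}{self.iterations_used}",
            f"{'Converged':<24}{self.converged}",
            f"{'Relative error':<24}{self.relative_error:.6g}",
            f"{'RMSE':<24}{self.rmse:.6g}",
            f"{'Reconstruction SNR':<24}{self.snr:.4f} dB",
            "=" * 41,
            f"init={self.config['init']}, norm={self.config['norm']}, "
            f"tol={self.config['tol']:g}, seed={self.config['seed']}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<CSNMFResults k={self.model.k} iters={self.iterations_used} "
            f"rel_err={self.relative_error:.4g} converged={self.converged}>"
        )
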