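# Methods

## Model

`csnmf` estimates the co-sparse non-negative factorization

    min ||X − W H||²_F   s.t.  W ≥ 0, H ≥ 0,
                               nnz(H) ≤ ⌊α·K·N⌋,  nnz(W) ≤ ⌊β·D·K⌋,

for a non-negative D × N matrix X and a chosen inner dimension K.  The
budgets are *global* over each factor (not per column), so columns may
carry unequal numbers of non-zeros.  Budgets are floored and clamped to
at least 1; a level of 1 disables the corresponding constraint, and
α = β = 1 reduces the problem to classical NMF solved by alternating
non-negative least squares.

## Solver

The solver alternates one primal–dual active-set (PDAS) pass per factor
per outer iteration.  A pass on H (the W pass is the same applied to
the transposed problem Xᵀ ≈ Hᵀ Wᵀ):

1. **Coordinate candidates.**  For every entry, the unconstrained
   minimizer of the loss in that entry alone, in closed form
   `H* = H + Wᵀ(X − WH) / ||W·p||²` (row-wise division by squared
   column norms of W).  For active entries this is ≈ the current value
   (their restricted gradient is ~0); for inactive entries it carries
   the dual information (scaled negative gradient), so primal and dual
   variables are screened on one common scale.
2. **Sacrifices.**  `Δ = ||W·p||² (H*)²` where `H* ≥ 0`, else 0.  A
   negative candidate would be clipped by the non-negativity constraint
   anyway, so pinning it to zero sacrifices nothing.
3. **Active set.**  The budget-many largest sacrifices.  Ties at the
   threshold break by stable row-major index order; zero-sacrifice
   entries are never activated, so the active set may undershoot the
   budget.  Both choices make runs bit-reproducible and keep the
   budget an upper bound.
4. **Restricted refit.**  Active entries solve each column's reduced
   NNLS problem exactly; inactive entries are bit-exact zeros.

All multi-column NNLS solves go through a fast combinatorial NNLS
(FC-NNLS) engine working on the normal equations: columns are batched
by passive-set size into stacked LU solves, feasibility backtracking
and dual (KKT) screening are vectorized across columns, and a masked
variant constrains every passive set to a per-column support — which is
how the restricted refit solves all N columns in one call.  Dual
tolerance is 1e-10 (scaled by the data magnitude); rank-deficient
passive blocks fall back to a least-norm solve with a warning.

**Update order.**  H is updated first when α ≤ β, W first otherwise
(the tie goes to H, matching the listing order of the update rules).

**Re-calibration.**  Before the first iteration H is refit by
unrestricted FC-NNLS on the initial W (`recalibrate=True` default).
This matters: the first support selection is then based on a coherent
(W, H) pair.  Without it the first PDAS pass screens a random H and
the fit can collapse onto a tiny support it never escapes.

**Normalization.**  After each W update the columns of W are
normalized — L1 (column sums, the default) or L2 — except on the final
iteration when the order is H-then-W, so the returned pair reproduces
X without rescaling.  By default the inverse scales are applied to the
rows of H (`compensate_h=True`), preserving the product WH across the
normalization.  This deviates from the bare update listing, which
rescales W only; we found that without compensation the next support
selection works from an inconsistent iterate and the error trajectory
oscillates indefinitely instead of settling.  `compensate_h=False`
restores the literal behaviour.

**Dead atoms.**  If a column of W becomes all-zero its sacrifices are
zero forever: death is absorbing under the literal rules, and on the
binary-shapes design roughly half the atoms can die from a random
start, capping the reconstruction SNR far below what the design
supports.  `reinit_dead_atoms=True` redraws dead columns from U(0, 1)
after each W update (clipped back to the last active set if it happens
on the final iteration, so the W budget always holds at return).  The
library default is off (the literal algorithm); the experiment harness
and the acceptance runs switch it on.

**Stopping.**  The loop stops when the relative Frobenius error
`||X − WH||_F / ||X||_F` reaches `tol` or after `max_iter` iterations.
Defaults: `tol=1e-4`, `max_iter=200`.  On noisy data the error floors
at the noise level, so `max_iter` is the effective budget and
`converged=False` just records that the floor is above `tol`.

**Initialization.**  `uniform` (i.i.d. U(0,1)), `subsample` (entries
resampled from X), or `svd` (split-sign rank-K SVD with zeros replaced
by a small positive constant).  One seed drives all randomness of a
fit.  The sparse problem is non-convex and a single fit can land in a
duplicated-atom optimum (two estimated columns covering one true basis
vector); `csnmf.experiments.fit_best_of` therefore fits with up to
five initializations (uniform ×2, subsample ×2, svd) and keeps the
lowest relative error — selection uses only the solver's own
objective, never ground truth.

## Synthetic designs

* **sim1** (sparse coding): D=60, N=1000, K ∈ {40, 60, 80}; dense
  half-normal basis with unit-L2 columns; H sparse at level α=0.2 with
  half-normal values.
* **sim2** (sparse shapes): twenty distinct 10×10 binary patterns
  (random rectangles, crosses and connected blobs — programmatic
  stand-ins with the same density and distinctness as a fixed shape
  catalogue) at exactly 10 ones each, stacked as 100-dim columns;
  dense half-normal H with N=100.
* **sim3** (co-sparse): D=N=300, K=60; both factors sparse at levels
  α, β ∈ {0.2, 0.4, 0.6} with chi-square(1) values; W columns
  normalized to unit L2 length.

Sparse factors place exactly ⌊level·rows·cols⌋ non-zeros, sampled
without replacement, so budgets and true sparsity match exactly.
Noise is `E = E0 · diag(S_WH / (10^{s/10} S_E0))` with E0 ~ U(0,1):
every noise column's sum is exactly `10^{−s/10}` times the signal
column's sum (machine precision), which the tests verify.  The
generators emulate the *statistical* structure of the designs — they do
not produce images with meaningful shapes, spatial correlation, or the
non-stationary intensity profiles of real scans, so passing tests
demonstrate correct behaviour under the stated random-matrix
conditions, not performance on real neuroimaging data.

## Metrics

Reconstruction SNR `10·log10(||X||²_F / ||X − WH||²_F)` (∞ for a zero
residual), RMSE defined as the plain residual Frobenius norm (no
divisor), and basis distance `||Ŵ_π − W||_F` where π is the optimal
column assignment under squared-Euclidean distances (exact Hungarian
solve).  Alignment defaults on — the factorization is only defined up
to column permutation.  An optional rescale normalizes both bases to
unit columns first; distances are only meaningful when estimate and
reference share a scale convention, which is why the experiment
harness fits with `norm='l2'` (the true bases are unit-L2).

A trajectory's *stabilization iteration* is the first iteration after
which five successive absolute changes all stay below 0.1% of the
final value.

## Problem sizes used by the test suite and acceptance script

The acceptance script averages the sim2 reconstruction SNR over 5
seeds (80 iterations each) and takes the worst stabilization iteration
over 10 sim1 replications (120 iterations each); the full run takes
about 15 s on one CPU.  The basis-recovery trend test runs sim1 at
K=40 with 3 replications per s ∈ {10, 30, 50} at the design's full 300
iterations, and sim3 with 10 paired replications at s ∈ {5, 50}; the
oracle-equivalence test compares 50 tiny instances (D, N ≤ 5, K ≤ 3,
budget ≤ 4) against exhaustive support enumeration.

## Known limitations

* The joint problem is non-convex; single fits can converge to
  duplicated-atom optima.  Restarts mitigate but do not eliminate
  this.
* Stabilization of the error trajectory is data-dependent: in a
  fraction of sparse-coding replications the fit keeps improving at
  ~0.1–0.2% of the final RMSE per iteration well past iteration 80
  (monotonically — these are genuine gains, reaching below the
  generator's noise floor), so the measured stabilization iteration
  can equal the iteration cap.  Classical alternating NNLS (α=β=1)
  behaves the same way on the same data.
* No automatic selection of K, α or β; the budgets are user inputs.
* The exhaustive oracles are exponential and guarded to toy sizes;
  they exist for verification only.
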