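"""Synthetic data generators for the three validation designs.

Three study designs are emulated:

* **sim1** — sparse coding matrix: dense half-normal basis with
  unit-L2 columns (D=60), sparse half-normal H (level ``alpha=0.2``),
  N=1000, K in {40, 60, 80}.
* **sim2** — sparse binary "shape" basis: 20 distinct 10x10 binary
  patterns at 10% density stacked as 100-dim columns, dense half-normal
  H, N=100.
* **sim3** — co-sparse: both factors sparse with chi-square(1) values
  (levels ``alpha``, ``beta`` in {0.2, 0.4, 0.6}), unit-L2 basis
  columns, D=N=300, K=60.

Noise is added column-wise at a prescribed true SNR ``s`` (dB):
``E = E0 diag(S_WH / (10^{s/10} S_E0))`` with ``E0 ~ U(0,1)``, so every
noise column's sum is exactly ``10^{-s/10}`` times the signal column's
sum.  Non-zero positions in sparse factors are sampled uniformly
without replacement, making the non-zero counts exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SimDesign",
    "gen_sparse_factor",
    "gen_shape_basis",
    "gen_noise",
    "make_dataset",
]


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one synthetic dataset.

    ``snr_db`` is the true signal-to-noise ratio s of the noise
    construction (noiseless limit as s -> inf); ``alpha`` and ``beta``
    are the sparsity levels of the TRUE coding and basis matrices.
    """

    scenario: str
    d: int
    n: int
    k: int
    alpha: float
    beta: float
    snr_db: float
    value_dist: str
    seed: int = 0
    shape_side: int = 10
    shape_density: float = 0.1

    @classmethod
    def sim1(cls, k=40, snr_db=20.0, seed=0, d=60, n=1000, alpha=0.2):
        return cls("sim1", d, n, k, alpha, 1.0, snr_db, "abs_gauss", seed)

    @classmethod
    def sim2(cls, snr_db=20.0, seed=0, k=20, n=100, side=10, density=0.1):
        return cls(
            "sim2", side * side, n, k, 1.0, density, snr_db, "shapes",
            seed, shape_side=side, shape_density=density,
        )

    @classmethod
    def sim3(cls, alpha=0.2, beta=0.2, snr_db=20.0, seed=0, d=300, n=300, k=60):
        return cls("sim3", d, n, k, alpha, beta, snr_db, "abs_chisq1", seed)

    def with_seed(self, seed):
        return replace(self, seed=seed)


def gen_sparse_factor(rows, cols, sparsity, dist="abs_gauss", seed=None):
    """Sparse non-negative matrix with an exact non-zero count.

    Exactly ``floor(sparsity * rows * cols)`` entries are non-zero;
    positions are drawn uniformly without replacement and filled with
    |N(0, 1)| (``abs_gauss``) or chi-square(1) (``abs_chisq1``) values.
    """
    if sparsity <= 0:
        raise ValueError("sparsity must be positive")
    if sparsity > 1:
        raise ValueError("sparsity cannot exceed 1")
    rng = _as_rng(seed)
    size = rows * cols
    nnz = int(np.floor(sparsity * size))
    flat = np.zeros(size)
    pos = rng.choice(size, size=nnz, replace=False)
    if dist == "abs_gauss":
        vals = np.abs(rng.standard_normal(nnz))
    elif dist == "abs_chisq1":
        vals = rng.chisquare(1.0, size=nnz)
    else:
        raise ValueError(f"unknown value distribution {dist!r}")
    flat[pos] = vals
    return flat.reshape(rows, cols)


def _shape_rect(side, k, rng):
    h_min = -(-k // side)  # ceil(k / side)
    h = int(rng.integers(h_min, side + 1))
    w = -(-k // h)
    r0 = int(rng.integers(0, side - h + 1))
    c0 = int(rng.integers(0, side - w + 1))
    img = np.zeros((side, side), dtype=np.uint8)
    cells = [(r0 + i, c0 + j) for i in range(h) for j in range(w)][:k]
    for r, c in cells:
        img[r, c] = 1
    return img


def _shape_cross(side, k, rng):
    if k > 2 * side - 1:
        return _shape_blob(side, k, rng)
    r0 = int(rng.integers(0, side))
    c0 = int(rng.integers(0, side))
    cells = [(r0, c) for c in range(side)] + [
        (r, c0) for r in range(side) if r != r0
    ]
    cells.sort(key=lambda rc: (abs(rc[0] - r0) + abs(rc[1] - c0), rc))
    img = np.zeros((side, side), dtype=np.uint8)
    for r, c in cells[:k]:
        img[r, c] = 1
    return img


def _shape_blob(side, k, rng):
    img = np.zeros((side, side), dtype=np.uint8)
    start = (int(rng.integers(0, side)), int(rng.integers(0, side)))
    chosen = {start}
    frontier = set()

    def neighbors(rc):
        r, c = rc
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < side and 0 <= cc < side:
                yield rr, cc

    frontier.update(n for n in neighbors(start))
    while len(chosen) < k:
        pool = sorted(frontier - chosen)
        nxt = pool[int(rng.integers(0, len(pool)))]
        chosen.add(nxt)
        frontier.update(neighbors(nxt))
    for r, c in chosen:
        img[r, c] = 1
    return img


def gen_shape_basis(num_shapes, side=10, density=0.1, seed=None):
    """Binary basis of distinct structured patterns.

    Returns a ``(side**2, num_shapes)`` 0/1 matrix; each column is a
    structured binary pattern (rectangles, crosses and connected blobs,
    cycled) with exactly ``round(density * side**2)`` ones, and columns
    are pairwise distinct.
    """
    if density <= 0 or density > 1:
        raise ValueError("density must be in (0, 1]")
    k = int(round(density * side * side))
    if k < 1:
        raise ValueError("density * side^2 must be at least 1")
    rng = _as_rng(seed)
    makers = (_shape_rect, _shape_cross, _shape_blob)
    cols = []
    seen = set()
    for i in range(num_shapes):
        for attempt in range(500):
            maker = makers[(i + attempt) % len(makers)]
            img = maker(side, k, rng)
            key = img.tobytes()
            if key not in seen:
                seen.add(key)
                cols.append(img.ravel())
                break
        else:
            raise RuntimeError(
                "could not generate enough distinct shapes; "
                "increase side or density"
            )
    return np.column_stack(cols).astype(float)


def gen_noise(WH, snr_db, seed=None):
    """Column-sum-scaled uniform noise at a true SNR of ``snr_db`` dB.

    ``E = E0 diag(S_WH / (10^{s/10} S_E0))`` with ``E0 ~ U(0, 1)``, so
    ``sum(E[:, j]) = sum(WH[:, j]) * 10^{-s/10}`` holds exactly for
    every column; all-zero signal columns yield all-zero noise columns.
    """
    WH = np.asarray(WH, dtype=float)
    if (WH < 0).any():
        raise ValueError("WH must be non-negative")
    rng = _as_rng(seed)
    d, n = WH.shape
    E0 = rng.uniform(size=(d, n))
    col_sums = E0.sum(axis=0)
    while (col_sums == 0.0).any():  # probability-zero guard
        redo = col_sums == 0.0
        E0[:, redo] = rng.uniform(size=(d, int(redo.sum())))
        col_sums = E0.sum(axis=0)
    s_wh = WH.sum(axis=0)
    scale = s_wh / (10.0 ** (snr_db / 10.0) * col_sums)
    return E0 * scale


def _unit_columns(W):
    norms = np.linalg.norm(W, axis=0)
    return W / np.where(norms > 0, norms, 1.0)


def make_dataset(design):
    """Generate one dataset ``X = W H + E`` for a :class:`SimDesign`.

    Returns ``(X, W_true, H_true)``.  True basis columns are unit-L2
    (sim1/sim3) or binary shapes (sim2); the true coding matrix is
    sparse at level ``alpha`` except in sim2 where it is dense.
    """
    rng = _as_rng(design.seed)
    rng_w, rng_h, rng_e = rng.spawn(3)
    if design.scenario == "sim1":
        W = _unit_columns(np.abs(rng_w.standard_normal((design.d, design.k))))
        H = gen_sparse_factor(design.k, design.n, design.alpha, "abs_gauss", rng_h)
    elif design.scenario == "sim2":
        W = gen_shape_basis(
            design.k, design.shape_side, design.shape_density, rng_w
        )
        H = np.abs(rng_h.standard_normal((design.k, design.n)))
    elif design.scenario == "sim3":
        W = _unit_columns(
            gen_sparse_factor(design.d, design.k, design.beta, "abs_chisq1", rng_w)
        )
        H = gen_sparse_factor(design.k, design.n, design.alpha, "abs_chisq1", rng_h)
    else:
        raise ValueError(f"unknown scenario {design.scenario!r}")
    WH = W @ H
    E = gen_noise(WH, design.snr_db, rng_e)
    return WH + E, W, H
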