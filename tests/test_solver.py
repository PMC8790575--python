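"""Unit tests for the APDAS building blocks."""

import numpy as np
import pytest

from csnmf import (
    coordinate_optimum,
    init_factors,
    normalize_columns,
    recalibrate,
    relative_error,
    sacrifice,
    select_active,
    sparse_nnls,
    update_h,
    update_w,
)


# ---------------------------------------------------------------- candidates

def test_coordinate_optimum_unit_axis_projection():
    W = np.array([[1.0], [0.0]])
    H = np.array([[0.0]])
    X = np.array([[3.0], [5.0]])
    cand, norms = coordinate_optimum(X, W, H)
    np.testing.assert_allclose(cand, [[3.0]])
    np.testing.assert_allclose(norms, [1.0])


def test_coordinate_optimum_least_squares_fixed_point():
    rng = np.random.default_rng(0)
    W = rng.uniform(size=(6, 3))
    X = rng.uniform(size=(6, 4))
    H_ls = np.linalg.lstsq(W, X, rcond=None)[0]
    cand, _ = coordinate_optimum(X, W, H_ls)
    np.testing.assert_allclose(cand, H_ls, atol=1e-10)


def test_coordinate_optimum_against_grid_search():
    """Each candidate minimizes the partial loss over a dense scalar grid."""
    rng = np.random.default_rng(1)
    W = rng.uniform(size=(4, 3))
    H = rng.uniform(size=(3, 5))
    X = rng.uniform(size=(4, 5))
    cand, _ = coordinate_optimum(X, W, H)
    grid = np.linspace(-3.0, 3.0, 1201)
    for p in range(3):
        for t in range(5):
            losses = []
            for v in grid:
                Hv = H.copy()
                Hv[p, t] = v
                losses.append(np.sum((X - W @ Hv) ** 2))
            best = grid[int(np.argmin(losses))]
            assert abs(cand[p, t] - best) <= (grid[1] - grid[0])


def test_coordinate_optimum_dead_atom_reports_zero():
    W = np.array([[1.0, 0.0], [1.0, 0.0]])
    H = np.ones((2, 2))
    X = np.ones((2, 2))
    cand, norms = coordinate_optimum(X, W, H)
    assert norms[1] == 0.0
    assert (cand[1] == 0.0).all()


def test_coordinate_optimum_shape_mismatch():
    with pytest.raises(ValueError):
        coordinate_optimum(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 2)))


# ---------------------------------------------------------------- sacrifices

def test_sacrifice_values_and_clamping():
    delta = sacrifice(np.array([1.0]), np.array([[2.0]]))
    assert delta[0, 0] == pytest.approx(4.0)
    assert sacrifice(np.array([5.0]), np.array([[-1.0]]))[0, 0] == 0.0
    assert sacrifice(np.array([0.0]), np.array([[3.0]]))[0, 0] == 0.0


def test_sacrifice_rejects_negative_norms():
    with pytest.raises(ValueError):
        sacrifice(np.array([-1.0]), np.array([[1.0]]))


def test_select_active_top_budget():
    delta = np.array([[5.0, 3.0], [1.0, 0.0]])
    mask = select_active(delta, 2)
    assert mask.tolist() == [[True, True], [False, False]]


def test_select_active_row_major_tie_break():
    delta = np.array([[2.0, 2.0], [2.0, 0.0]])
    mask = select_active(delta, 2)
    assert mask.tolist() == [[True, True], [False, False]]


def test_select_active_excludes_zero_sacrifices():
    delta = np.array([[0.0, 4.0], [0.0, 0.0]])
    mask = select_active(delta, 3)
    assert mask.sum() == 1 and mask[0, 1]


def test_select_active_rejects_nonpositive_budget():
    with pytest.raises(ValueError):
        select_active(np.ones((2, 2)), 0)


# ------------------------------------------------------------------- updates

def test_update_h_zeroes_inactive_and_solves_active():
    W = np.eye(2)
    X = np.array([[3.0], [1.0]])
    mask = np.array([[True], [False]])
    H = update_h(X, W, mask)
    np.testing.assert_allclose(H, [[3.0], [0.0]])
    mask_all = np.ones((2, 1), dtype=bool)
    np.testing.assert_allclose(update_h(X, W, mask_all), [[3.0], [1.0]])


def test_update_w_mirror_and_empty_row():
    H = np.eye(2)
    X = np.array([[4.0, 2.0]])
    W = update_w(X, H, np.ones((1, 2), dtype=bool))
    np.testing.assert_allclose(W, [[4.0, 2.0]])
    W0 = update_w(X, H, np.zeros((1, 2), dtype=bool))
    assert (W0 == 0.0).all()


def test_update_w_is_transposed_update_h():
    rng = np.random.default_rng(4)
    X = rng.uniform(size=(5, 6))
    H = rng.uniform(size=(3, 6))
    mask = rng.uniform(size=(5, 3)) < 0.6
    W = update_w(X, H, mask)
    Wt = update_h(X.T, H.T, mask.T)
    np.testing.assert_allclose(W, Wt.T)


# ------------------------------------------------------- normalization, error

def test_normalize_columns_l1():
    W = np.array([[2.0, 0.0], [2.0, 0.0]])
    Wn, scales = normalize_columns(W, "l1")
    np.testing.assert_allclose(Wn[:, 0], [0.5, 0.5])
    np.testing.assert_allclose(scales, [4.0, 1.0])
    assert (Wn[:, 1] == 0.0).all()  # zero column untouched
    Wn2, scales2 = normalize_columns(Wn, "l1")
    np.testing.assert_allclose(Wn2, Wn)
    np.testing.assert_allclose(scales2, [1.0, 1.0])


def test_normalize_columns_l2_and_bad_norm():
    W = np.array([[3.0], [4.0]])
    Wn, scales = normalize_columns(W, "l2")
    np.testing.assert_allclose(np.linalg.norm(Wn[:, 0]), 1.0)
    np.testing.assert_allclose(scales, [5.0])
    with pytest.raises(ValueError):
        normalize_columns(W, "linf")


def test_relative_error_cases():
    X = np.array([[2.0]])
    assert relative_error(X, np.array([[1.0]]), np.array([[2.0]])) == 0.0
    assert relative_error(X, np.array([[0.0]]), np.array([[0.0]])) == 1.0
    assert relative_error(X, np.array([[1.0]]), np.array([[1.0]])) == 0.5
    with pytest.raises(ValueError):
        relative_error(np.zeros((2, 2)), np.ones((2, 1)), np.ones((1, 2)))


# ------------------------------------------------------------ initialization

def test_init_uniform_range_and_shapes():
    X = np.ones((3, 4))
    W, H = init_factors(X, 2, "uniform", seed=0)
    assert W.shape == (3, 2) and H.shape == (2, 4)
    assert ((W > 0) & (W < 1)).all() and ((H > 0) & (H < 1)).all()


def test_init_subsample_constant_matrix():
    X = np.full((3, 4), 7.0)
    W, H = init_factors(X, 2, "subsample", seed=1)
    assert (W == 7.0).all() and (H == 7.0).all()


def test_init_svd_rank_one_recovers_direction():
    rng = np.random.default_rng(3)
    w = rng.uniform(0.5, 1.5, size=5)
    h = rng.uniform(0.5, 1.5, size=6)
    X = np.outer(w, h)
    W0, H0 = init_factors(X, 1, "svd", seed=0)
    # compare against a direct rank-1 SVD oracle, up to scale
    U, S, Vt = np.linalg.svd(X)
    cos_w = abs(W0[:, 0] @ np.abs(U[:, 0])) / np.linalg.norm(W0[:, 0])
    cos_h = abs(H0[0] @ np.abs(Vt[0])) / np.linalg.norm(H0[0])
    assert cos_w > 1 - 1e-10 and cos_h > 1 - 1e-10


def test_init_errors():
    X = np.ones((3, 3))
    with pytest.raises(ValueError):
        init_factors(X, 0, "uniform")
    with pytest.raises(ValueError):
        init_factors(np.zeros((3, 3)), 1, "svd")
    with pytest.raises(ValueError):
        init_factors(X, 5, "svd")  # only one non-trivial singular triplet


def test_init_seeded_determinism():
    X = np.arange(12.0).reshape(3, 4) + 1
    a = init_factors(X, 2, "uniform", seed=9)
    b = init_factors(X, 2, "uniform", seed=9)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ------------------------------------------------------------- recalibration

def test_recalibrate_identity_design_gives_data():
    X = np.array([[1.0, 2.0], [3.0, 4.0]])
    W = np.eye(2)
    _, H = recalibrate(X, W, np.zeros((2, 2)))
    np.testing.assert_allclose(H, X, atol=1e-10)


def test_recalibrate_recovers_true_coding_full_rank():
    rng = np.random.default_rng(6)
    W = rng.uniform(0.2, 1.0, size=(6, 3))
    H_true = rng.uniform(size=(3, 5))
    X = W @ H_true
    _, H = recalibrate(X, W, rng.uniform(size=(3, 5)))
    np.testing.assert_allclose(H, H_true, atol=1e-8)


def test_recalibrate_zero_design_column_gives_zero_row():
    W = np.array([[1.0, 0.0], [1.0, 0.0]])
    X = np.ones((2, 3))
    _, H = recalibrate(X, W, np.ones((2, 3)))
    assert (H[1] == 0.0).all()


# ------------------------------------------------------------- sparse coding

def test_sparse_nnls_exact_support_recovery():
    rng = np.random.default_rng(12)
    W = rng.uniform(0.2, 1.0, size=(5, 3))
    H_true = np.zeros((3, 4))
    H_true[0, 0] = 1.2
    H_true[2, 3] = 0.8
    X = W @ H_true
    H, mask = sparse_nnls(W, X, 2)
    np.testing.assert_allclose(H, H_true, atol=1e-8)
    assert mask.sum() <= 2
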