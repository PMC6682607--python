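import numpy as np
import pytest

from parcelmkl.kernels import KernelStack, build_kernel_stack
from parcelmkl.mkl import (
    extract_weight_maps,
    predict,
    simple_mkl_fit,
    solve_svr_dual,
)
from parcelmkl.nifti import Grid, Parcellation, VoxelDataset

from _oracles import svr_dual_qp


def _stack_from_matrix(X, region_cols, train_index=None):
    """Build a KernelStack directly from a feature matrix and column groups."""
    n, p = X.shape
    shape = (p, 1, 1)
    coords = np.column_stack(np.unravel_index(np.arange(p), shape))
    ds = VoxelDataset(np.asarray(X, float), [f"s{i}" for i in range(n)],
                      Grid(shape, np.eye(4)), coords)
    labels = np.zeros(shape, int)
    region_voxels = {}
    for rid, cols in region_cols.items():
        labels.ravel()[cols] = rid
        region_voxels[rid] = np.asarray(cols)
    parc = Parcellation(labels, {r: str(r) for r in region_cols}, region_voxels)
    tr = np.arange(n) if train_index is None else np.asarray(train_index)
    return ds, parc, build_kernel_stack(ds, parc, tr, keep_features=True)


class TestSvrDual:
    def test_zero_targets_give_zero_solution(self):
        K = np.eye(4)
        beta, b, J = solve_svr_dual(K, np.zeros(4), C=1.0, epsilon=0.1)
        assert np.allclose(beta, 0) and b == 0 and J == 0

    def test_three_points_on_line_interpolated(self):
        x = np.array([[0.0], [1.0], [2.0]])
        K = x @ x.T
        y = 2.0 * x.ravel() + 1.0
        beta, b, J = solve_svr_dual(K, y, C=1e6, epsilon=0.0)
        yhat = K @ beta + b
        assert np.allclose(yhat, y, atol=1e-6)

    @pytest.mark.parametrize("C,epsilon", [(1.0, 0.1), (10.0, 0.0), (0.5, 0.3)])
    def test_matches_generic_qp_oracle(self, C, epsilon):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((6, 4))
        K = X @ X.T
        y = rng.standard_normal(6) * 2
        beta, b, J = solve_svr_dual(K, y, C=C, epsilon=epsilon)
        beta_o, b_o, J_o = svr_dual_qp(K, y, C, epsilon)
        assert J == pytest.approx(J_o, abs=1e-6)
        assert np.allclose(beta, beta_o, atol=1e-4)

    def test_dual_constraints_hold(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        C = 0.7
        beta, b, J = solve_svr_dual(X @ X.T, y, C=C, epsilon=0.05)
        assert np.all(np.abs(beta) <= C + 1e-8)
        assert beta.sum() == pytest.approx(0.0, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            solve_svr_dual(np.eye(3), np.ones(3), C=-1.0, epsilon=0.1)
        with pytest.raises(ValueError):
            solve_svr_dual(np.eye(3), np.ones(3), C=1.0, epsilon=-0.1)

    def test_non_psd_kernel_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="semidefinite"):
            solve_svr_dual(K, np.array([1.0, -1.0]), C=1.0, epsilon=0.1)


class TestSimpleMkl:
    def test_single_region_equals_plain_svr(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((10, 6))
        y = rng.standard_normal(10) * 3 + 5
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(6)})
        fit = simple_mkl_fit(stack, y, C=2.0, epsilon=0.1)
        assert fit.kernel_weights == {1: 1.0}
        beta, b, _ = solve_svr_dual(stack.train_block(1), y - y.mean(), 2.0, 0.1)
        yhat_direct = stack.train_block(1) @ beta + b + y.mean()
        assert np.allclose(predict(fit, stack, np.arange(10)), yhat_direct, atol=1e-6)

    def test_two_identical_kernels_match_single_kernel_fit(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((8, 4))
        y = rng.standard_normal(8)
        Xdup = np.hstack([X, X])
        ds, parc, stack2 = _stack_from_matrix(Xdup, {1: np.arange(4), 2: np.arange(4, 8)})
        ds1, parc1, stack1 = _stack_from_matrix(X, {1: np.arange(4)})
        fit2 = simple_mkl_fit(stack2, y, C=1.0, epsilon=0.1)
        fit1 = simple_mkl_fit(stack1, y, C=1.0, epsilon=0.1)
        assert np.allclose(predict(fit2, stack2, np.arange(8)),
                           predict(fit1, stack1, np.arange(8)), atol=1e-6)

    def test_simplex_and_box_invariants(self, small_inputs):
        ds, parc, table = small_inputs
        tr = np.arange(20)
        stack = build_kernel_stack(ds, parc, tr)
        C = 1.5
        fit = simple_mkl_fit(stack, table.target[tr], C=C, epsilon=0.1)
        d = np.array(list(fit.kernel_weights.values()))
        assert np.all(d >= 0)
        assert d.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.abs(fit.dual_coef) <= C + 1e-8)
        assert fit.dual_coef.sum() == pytest.approx(0.0, abs=1e-6)

    def test_planted_signal_region_dominates_and_beats_grid(self):
        rng = np.random.default_rng(16)
        n = 24
        u = rng.standard_normal(n)
        X = np.empty((n, 12))
        X[:, :6] = np.outer(u, rng.choice([-1.0, 1.0], 6)) + 0.05 * rng.standard_normal((n, 6))
        X[:, 6:] = rng.standard_normal((n, 6))
        y = 3.0 * u + 0.1 * rng.standard_normal(n)
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(6), 2: np.arange(6, 12)})
        fit = simple_mkl_fit(stack, y, C=10.0, epsilon=0.1, tol=1e-6)
        assert fit.kernel_weights[1] > 0.9
        assert fit.region_ranking[0] == 1
        # learned mixture is at least as good as a fine simplex grid
        yc = y - y.mean()
        best_grid = min(
            solve_svr_dual(
                a * stack.train_block(1) + (1 - a) * stack.train_block(2),
                yc, 10.0, 0.1,
            )[2]
            for a in np.linspace(0, 1, 101)
        )
        assert fit.objective <= best_grid + 1e-6

    def test_zero_weight_regions_contribute_nothing(self):
        rng = np.random.default_rng(17)
        n = 16
        u = rng.standard_normal(n)
        X = np.empty((n, 9))
        X[:, :3] = np.outer(u, [1, -1, 1])
        X[:, 3:] = rng.standard_normal((n, 6))
        y = 2.0 * u
        ds, parc, stack = _stack_from_matrix(
            X, {1: np.arange(3), 2: np.arange(3, 6), 3: np.arange(6, 9)}
        )
        fit = simple_mkl_fit(stack, y, C=10.0, epsilon=0.05, tol=1e-6)
        zero_regions = [r for r, d in fit.kernel_weights.items() if d == 0]
        assert zero_regions, "expected sparsity"
        pred_full = predict(fit, stack, np.arange(n))
        pruned = KernelStack(
            {r: K for r, K in stack.kernels.items() if fit.kernel_weights[r] > 0},
            stack.norm_constants, stack.center_stats, stack.train_index,
            stack.region_voxels,
        )
        fit_pruned = type(fit)(
            kernel_weights={r: d for r, d in fit.kernel_weights.items() if d > 0},
            dual_coef=fit.dual_coef, bias=fit.bias, C=fit.C, epsilon=fit.epsilon,
            target_offset=fit.target_offset, train_index=fit.train_index,
        )
        assert np.allclose(predict(fit_pruned, pruned, np.arange(n)), pred_full,
                           atol=1e-10)

    def test_objective_convex_along_simplex_segments(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((10, 8))
        y = rng.standard_normal(10)
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(4), 2: np.arange(4, 8)})
        yc = y - y.mean()

        def J(a):
            K = a * stack.train_block(1) + (1 - a) * stack.train_block(2)
            return solve_svr_dual(K, yc, 1.0, 0.1)[2]

        for a0, a1 in [(0.0, 1.0), (0.2, 0.8), (0.1, 0.5)]:
            mid = J((a0 + a1) / 2)
            assert mid <= (J(a0) + J(a1)) / 2 + 1e-8

    def test_duplicated_kernel_leaves_performance_unchanged(self):
        rng = np.random.default_rng(19)
        n = 20
        u = rng.standard_normal(n)
        X = np.empty((n, 8))
        X[:, :4] = np.outer(u, rng.choice([-1.0, 1.0], 4)) + 0.1 * rng.standard_normal((n, 4))
        X[:, 4:] = rng.standard_normal((n, 4))
        y = u * 2
        tr = np.arange(14)
        te = np.arange(14, 20)
        ds, parc, st = _stack_from_matrix(X, {1: np.arange(4), 2: np.arange(4, 8)}, tr)
        Xd = np.hstack([X, X[:, :4]])
        dsd, parcd, std = _stack_from_matrix(
            Xd, {1: np.arange(4), 2: np.arange(4, 8), 3: np.arange(8, 12)}, tr
        )
        fit = simple_mkl_fit(st, y[tr], C=5.0, epsilon=0.1, tol=1e-6)
        fitd = simple_mkl_fit(std, y[tr], C=5.0, epsilon=0.1, tol=1e-6)
        assert np.allclose(predict(fit, st, te), predict(fitd, std, te), atol=1e-3)


class TestPredict:
    def test_interpolation_regime_reproduces_training_targets(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((8, 8))  # full-rank: exact interpolation possible
        y = rng.standard_normal(8)
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(4), 2: np.arange(4, 8)})
        fit = simple_mkl_fit(stack, y, C=1e4, epsilon=0.0, tol=1e-8)
        assert np.allclose(predict(fit, stack, np.arange(8)), y, atol=1e-3)

    def test_duplicate_test_subject_gets_training_fitted_value(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((9, 6))
        X[8] = X[2]  # test subject identical to training subject 2
        y = rng.standard_normal(9)
        tr = np.arange(8)
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(3), 2: np.arange(3, 6)}, tr)
        fit = simple_mkl_fit(stack, y[tr], C=1.0, epsilon=0.1)
        preds = predict(fit, stack, np.array([2, 8]))
        assert preds[0] == pytest.approx(preds[1], abs=1e-10)

    def test_region_set_mismatch_rejected(self, toy_stack):
        from parcelmkl.mkl import MKLFit

        fit = MKLFit(kernel_weights={1: 0.5, 9: 0.5}, dual_coef=np.zeros(6),
                     bias=0.0, C=1.0, epsilon=0.1, target_offset=0.0,
                     train_index=np.arange(6))
        with pytest.raises(ValueError, match="mismatch"):
            predict(fit, toy_stack, np.arange(6))


class TestWeightMaps:
    def test_unselected_region_voxels_are_zero(self):
        rng = np.random.default_rng(22)
        n = 12
        u = rng.standard_normal(n)
        X = np.empty((n, 6))
        X[:, :3] = np.outer(u, [1.0, -1.0, 1.0])
        X[:, 3:] = rng.standard_normal((n, 3))
        y = u
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(3), 2: np.arange(3, 6)})
        fit = simple_mkl_fit(stack, y, C=10.0, epsilon=0.01, tol=1e-6)
        maps = extract_weight_maps(fit, ds, parc, stack)
        for rid, d in fit.kernel_weights.items():
            if d == 0:
                assert np.allclose(maps.voxel_weights[parc.region_voxels[rid]], 0.0)

    def test_primal_dual_prediction_equivalence(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((6, 8))
        y = rng.standard_normal(6)
        tr = np.arange(4)
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(4), 2: np.arange(4, 8)}, tr)
        fit = simple_mkl_fit(stack, y[tr], C=2.0, epsilon=0.1, tol=1e-7)
        maps = extract_weight_maps(fit, ds, parc, stack)
        kernel_preds = predict(fit, stack, np.arange(6))
        primal_preds = (stack.features @ maps.voxel_weights
                        + fit.bias + fit.target_offset)
        assert np.allclose(kernel_preds, primal_preds, atol=1e-6)

    def test_voxel_weights_scale_with_target(self):
        rng = np.random.default_rng(24)
        X = rng.standard_normal((10, 6))
        y = rng.standard_normal(10)
        ds, parc, stack = _stack_from_matrix(X, {1: np.arange(3), 2: np.arange(3, 6)})
        fit1 = simple_mkl_fit(stack, y, C=1.0, epsilon=0.1, tol=1e-7)
        fit2 = simple_mkl_fit(stack, 2 * y, C=2.0, epsilon=0.2, tol=1e-7)
        m1 = extract_weight_maps(fit1, ds, parc, stack)
        m2 = extract_weight_maps(fit2, ds, parc, stack)
        assert np.allclose(m2.voxel_weights, 2 * m1.voxel_weights, atol=1e-5)


def test_mkl_fit_json_round_trip():
    rng = np.random.default_rng(30)
    X = rng.standard_normal((10, 6))
    y = rng.standard_normal(10)
    ds, parc, stack = _stack_from_matrix(X, {1: np.arange(3), 2: np.arange(3, 6)})
    fit = simple_mkl_fit(stack, y, C=1.0, epsilon=0.1)
    from parcelmkl.mkl import MKLFit

    back = MKLFit.from_json(fit.to_json())
    assert back.kernel_weights == fit.kernel_weights
    assert np.allclose(back.dual_coef, fit.dual_coef)
    assert np.allclose(predict(back, stack, np.arange(10)),
                       predict(fit, stack, np.arange(10)))
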