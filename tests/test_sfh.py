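"""Plaintext SFH core: worked examples, oracles, and the Loewner-order
guarantees that make the fixed-Hessian simplification sound."""

import numpy as np
import pytest

from sfhlogit.sfh import (
    Dataset,
    ModelVector,
    _simplified_hessian_diag_counted,
    classify,
    fixed_hessian,
    gradient,
    invert_scalar_newton,
    irls_reference,
    log_likelihood,
    loewner_nonneg,
    newton_inversion_start,
    predict_proba,
    sfh_train,
    sigmoid,
    sigmoid_taylor,
    simplified_hessian_diag,
)


class TestDatasetInvariants:
    def test_rejects_missing_intercept(self):
        with pytest.raises(ValueError, match="intercept"):
            Dataset(np.array([[0.0, 1.0]]), np.array([1.0]))

    def test_rejects_bad_labels(self):
        with pytest.raises(ValueError, match="labels"):
            Dataset(np.array([[1.0, 1.0]]), np.array([2.0]))

    def test_from_covariates_prepends_ones(self):
        d = Dataset.from_covariates(np.array([[0.3], [0.7]]), [1, -1])
        assert np.all(d.X[:, 0] == 1.0) and d.d == 1 and d.N == 2


class TestSigmoid:
    def test_taylor_values(self):
        assert sigmoid_taylor(0.0) == 0.5
        assert sigmoid_taylor(2.0) == 1.0  # not clamped

    def test_taylor_error_vs_true_sigmoid(self):
        # at z=2 the affine approximation overshoots by ~0.119
        err = abs(sigmoid_taylor(2.0) - 1.0 / (1.0 + np.exp(-2.0)))
        assert err == pytest.approx(0.1192, abs=1e-4)


class TestLogLikelihood:
    def test_at_zero_is_minus_n_log2(self, small_binary_data):
        beta = ModelVector(np.zeros(small_binary_data.d + 1))
        assert log_likelihood(beta, small_binary_data) == pytest.approx(
            -small_binary_data.N * np.log(2.0)
        )

    def test_single_record_value(self):
        d = Dataset(np.array([[1.0, 1.0]]), np.array([1.0]))
        val = log_likelihood(ModelVector([0.0, 1.0]), d)
        assert val == pytest.approx(-np.log(1.0 + np.exp(-1.0)))

    def test_tends_to_zero_when_correctly_classified(self):
        d = Dataset(np.array([[1.0, 1.0]]), np.array([1.0]))
        vals = [log_likelihood(ModelVector([0.0, s]), d) for s in (1, 10, 100)]
        assert vals[0] < vals[1] < vals[2] <= 0.0
        assert vals[2] == pytest.approx(0.0, abs=1e-40)

    def test_dimension_mismatch(self, small_binary_data):
        with pytest.raises(ValueError):
            log_likelihood(ModelVector([0.0]), small_binary_data)


class TestGradient:
    def test_worked_example_both_modes(self, two_record_data):
        beta = ModelVector([0.0, 0.0])
        for mode in ("exact", "taylor"):
            g = gradient(beta, two_record_data, mode=mode)
            assert np.allclose(g, [0.0, 0.5])

    def test_taylor_at_zero_is_half_Xt_y(self, small_binary_data):
        beta = ModelVector(np.zeros(small_binary_data.d + 1))
        g = gradient(beta, small_binary_data, mode="taylor")
        expected = 0.5 * small_binary_data.X.T @ small_binary_data.y
        assert np.allclose(g, expected)

    def test_exact_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        X = rng.random((15, 4))
        X[:, 0] = 1.0
        data = Dataset(X, np.where(rng.random(15) < 0.5, 1.0, -1.0))
        beta = rng.normal(size=4)
        g = gradient(ModelVector(beta), data, mode="exact")
        eps = 1e-6
        for k in range(4):
            step = np.zeros(4)
            step[k] = eps
            fd = (
                log_likelihood(ModelVector(beta + step), data)
                - log_likelihood(ModelVector(beta - step), data)
            ) / (2 * eps)
            assert g[k] == pytest.approx(fd, abs=1e-6)


class TestHessianBounds:
    def test_fixed_hessian_worked_example(self, two_record_data):
        H = fixed_hessian(two_record_data)
        assert np.allclose(H, [[-0.5, -0.25], [-0.25, -0.25]])
        assert np.allclose(H, H.T)

    def test_intercept_only_diag(self):
        d = Dataset(np.ones((8, 1)), np.ones(8))
        assert np.allclose(simplified_hessian_diag(d), [-2.0])

    def test_diag_equals_row_sums_of_full(self, small_binary_data):
        H = fixed_hessian(small_binary_data)
        diag = simplified_hessian_diag(small_binary_data)
        assert np.allclose(diag, H.sum(axis=1), atol=1e-12)

    def test_diag_worked_example(self, two_record_data):
        assert np.allclose(
            simplified_hessian_diag(two_record_data), [-0.75, -0.5]
        )

    def test_bounds_container_is_consistent(self, small_binary_data):
        from sfhlogit.sfh import hessian_bounds

        b = hessian_bounds(small_binary_data)
        assert np.allclose(b.full, fixed_hessian(small_binary_data))
        assert np.allclose(b.diag, b.full.sum(axis=1))
        assert np.all(b.diag < 0.0)

    def test_rowsum_first_multiplication_count_linear_in_d(self):
        rng = np.random.default_rng(4)
        counts = {}
        for d in (3, 6, 12):
            X = (rng.random((20, d + 1)) < 0.4).astype(float)
            X[:, 0] = 1.0
            diag, mults = _simplified_hessian_diag_counted(X)
            assert mults <= 20 * (d + 2)
            assert np.allclose(
                diag, simplified_hessian_diag(Dataset(X, np.ones(20)))
            )
            counts[d] = mults
        # equal increments of d add equal increments of work: linear, not quadratic
        assert counts[12] - counts[6] == 2 * (counts[6] - counts[3])


class TestLoewnerOrder:
    def test_psd_and_not_psd(self):
        assert loewner_nonneg(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert not loewner_nonneg(np.array([[-1.0, 0.0], [0.0, 1.0]]))

    def test_rejects_non_symmetric(self):
        with pytest.raises(ValueError):
            loewner_nonneg(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_gerschgorin_diagonal_bound(self):
        # A - diag(rowsums(A)) is PSD for symmetric non-positive A
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            A = -rng.random((n, n))
            A = (A + A.T) / 2.0
            C = A - np.diag(A.sum(axis=1))
            assert np.linalg.eigvalsh(C).min() >= -1e-9

    @pytest.mark.parametrize("kind", ["binary", "uniform"])
    def test_loewner_chain_true_hessian_above_diag_bound(self, kind):
        # H(beta) >= Hbar >= Htilde for non-negative designs
        rng = np.random.default_rng(31)
        for _ in range(20):
            n, d = 25, int(rng.integers(2, 6))
            X = rng.random((n, d + 1))
            if kind == "binary":
                X = (X < 0.5).astype(float)
            X[:, 0] = 1.0
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            data = Dataset(X, y)
            beta = rng.normal(scale=0.8, size=d + 1)
            z = y * (X @ beta)
            s = sigmoid(z)
            H = -(X.T * (s * (1 - s))) @ X
            Hbar = fixed_hessian(data)
            Htilde = np.diag(simplified_hessian_diag(data))
            assert loewner_nonneg(H - Hbar, tol=1e-8)
            assert loewner_nonneg(Hbar - Htilde, tol=1e-8)


class TestNewtonReciprocal:
    def test_fixed_point(self):
        assert invert_scalar_newton(2.0, 0.5, 1) == 0.5

    def test_one_step_by_hand(self):
        assert invert_scalar_newton(4.0, 0.2, 1) == pytest.approx(0.24)

    def test_convergence(self):
        assert invert_scalar_newton(5.0, 0.1, 10) == pytest.approx(0.2, abs=1e-12)

    def test_error_squares_each_step(self):
        a, x = 3.0, 0.2
        for _ in range(4):
            prev = 1.0 - a * x
            x = invert_scalar_newton(a, x, 1)
            assert 1.0 - a * x == pytest.approx(prev**2, rel=1e-12)

    def test_start_value_rule_lies_in_basin(self):
        # a * x0 must land in (0, 2) for Htilde entries of typical data
        from sfhlogit.datasets import draw_beta, gen_synthetic

        rng = np.random.default_rng(3)
        for kind, mu in (("binary", 1.0), ("continuous", 0.5)):
            data = gen_synthetic(50, 8, kind, draw_beta(8, rng), seed=9)
            diag = simplified_hessian_diag(data)
            x0 = newton_inversion_start(data.N, data.d, mu)
            assert np.all(diag * x0 > 0.0) and np.all(diag * x0 < 2.0)


class TestSfhTrain:
    def test_two_record_worked_example(self, two_record_data):
        model = sfh_train(two_record_data, iters=1, inversion="exact")
        assert np.allclose(model.beta, [0.0, 1.0])

    def test_zero_iterations_returns_zero(self, small_binary_data):
        model = sfh_train(small_binary_data, iters=0)
        assert np.all(model.beta == 0.0)

    def test_zero_column_raises(self):
        X = np.ones((4, 2))
        X[:, 1] = 0.0
        with pytest.raises(ZeroDivisionError):
            sfh_train(Dataset(X, np.array([1.0, 1.0, -1.0, -1.0])), iters=1)

    def test_converges_to_taylor_gradient_fixed_point(self):
        from sfhlogit.datasets import draw_beta, gen_synthetic

        rng = np.random.default_rng(8)
        data = gen_synthetic(200, 4, "continuous", draw_beta(4, rng), seed=14)
        model = sfh_train(data, iters=3000, inversion="exact")
        g = gradient(model, data, mode="taylor")
        assert np.abs(g).max() < 1e-8

    def test_newton_mode_approaches_exact_mode_with_iterations(
        self, small_binary_data
    ):
        exact = sfh_train(small_binary_data, iters=1, inversion="exact")
        devs = [
            np.abs(
                sfh_train(
                    small_binary_data, iters=1, inversion="newton", inv_iters=k
                ).beta
                - exact.beta
            ).max()
            for k in (1, 4, 16)
        ]
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 1e-9


class TestIrlsReference:
    def test_intercept_only_closed_form(self):
        data = Dataset(np.ones((4, 1)), np.array([1.0, 1.0, 1.0, -1.0]))
        model = irls_reference(data)
        assert model.beta[0] == pytest.approx(np.log(3.0), abs=1e-6)

    def test_gradient_vanishes_at_optimum(self, small_binary_data):
        model = irls_reference(small_binary_data, tol=1e-10)
        g = gradient(model, small_binary_data, mode="exact")
        assert np.abs(g).max() < 1e-6

    def test_mle_dominates_sfh_likelihood(self, small_binary_data):
        mle = irls_reference(small_binary_data)
        sfh = sfh_train(small_binary_data, iters=1)
        assert log_likelihood(mle, small_binary_data) >= log_likelihood(
            sfh, small_binary_data
        )

    def test_separable_data_warns_and_caps(self):
        X = np.column_stack([np.ones(6), np.r_[np.zeros(3), np.ones(3)]])
        y = np.r_[-np.ones(3), np.ones(3)]
        with pytest.warns(RuntimeWarning):
            model = irls_reference(Dataset(X, y))
        assert np.all(np.abs(model.beta) <= 30.0)


class TestPrediction:
    def test_boundary_inclusive_at_default_threshold(self):
        p = predict_proba(ModelVector([0.0, 0.0]), [1.0, 0.3])
        assert p == 0.5
        assert classify(p) == 1  # p >= tau is +1

    def test_log3_gives_three_quarters(self):
        p = predict_proba(ModelVector([np.log(3.0), 0.0]), [1.0, 0.0])
        assert p == pytest.approx(0.75)

    def test_monotone_in_linear_predictor(self):
        beta = ModelVector([0.0, 1.0])
        ps = [predict_proba(beta, [1.0, z]) for z in (-2.0, 0.0, 2.0)]
        assert ps[0] < ps[1] < ps[2]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify(0.5, tau=1.0)
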