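"""Evidence-framework training: objective, LM steps, γ, (α, β) updates."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from brann.network import Architecture, Dataset, WeightVector, forward
from brann.regularize import (
    RegularizationState,
    TrainConfig,
    TrainingError,
    effective_parameters,
    gauss_newton_hessian,
    gradient,
    heritability,
    lm_step,
    log_evidence,
    objective,
    train,
    update_alpha_beta,
)
from brann.regularize import _state_at


def ridge_solution(x, t, lam):
    """Closed-form empirical-Bayes ridge oracle: (X'X + λI)⁻¹ X't."""
    return np.linalg.solve(x.T @ x + lam * np.eye(x.shape[1]), x.T @ t)


def linear_log_marginal(x, t, alpha, beta):
    """Exact Gaussian log-marginal likelihood for t = Xw + e with
    w ~ N(0, I/(2α)) and e ~ N(0, I/(2β))."""
    n = t.size
    cov = x @ x.T / (2 * alpha) + np.eye(n) / (2 * beta)
    return multivariate_normal(mean=np.zeros(n), cov=cov).logpdf(t)


@pytest.fixture
def linear_problem():
    rng = np.random.default_rng(10)
    n, m = 60, 12
    x = rng.normal(size=(n, m))
    w_true = rng.normal(size=m)
    t = x @ w_true + rng.normal(0, 0.6, n)
    t -= t.mean()
    return x, t


class TestObjective:
    def test_zero_weights_zero_targets(self):
        arch = Architecture.make_linear(3)
        data = Dataset(np.random.default_rng(0).normal(size=(4, 3)), np.zeros(4))
        f, e_d, e_w = objective(arch, np.zeros(3), data, 1.0, 1.0)
        assert f == e_d == e_w == 0.0

    def test_alpha_zero_reduces_to_weighted_rss(self):
        arch = Architecture.make_linear(2)
        rng = np.random.default_rng(1)
        data = Dataset(rng.normal(size=(5, 2)), rng.normal(size=5))
        w = rng.normal(size=2)
        f, e_d, _ = objective(arch, w, data, 0.0, 3.0)
        assert f == pytest.approx(3.0 * e_d)

    def test_hand_arithmetic(self):
        # residuals (1, -2), weights (0.5, 0.5), alpha=1, beta=2
        arch = Architecture.make_linear(2)
        x = np.eye(2)
        w = np.array([0.5, 0.5])
        t = x @ w + np.array([1.0, -2.0])
        f, e_d, e_w = objective(arch, w, Dataset(x, t), 1.0, 2.0)
        assert e_d == pytest.approx(5.0)
        assert e_w == pytest.approx(0.5)
        assert f == pytest.approx(10.5)


class TestGaussNewtonHessian:
    def test_zero_jacobian(self):
        h = gauss_newton_hessian(np.zeros((5, 3)), alpha=2.0, beta=1.0)
        np.testing.assert_allclose(h, 4.0 * np.eye(3))

    def test_identity_jacobian(self):
        h = gauss_newton_hessian(np.eye(4), alpha=1.0, beta=1.0)
        np.testing.assert_allclose(h, 4.0 * np.eye(4))

    def test_matches_finite_difference_hessian_for_linear_model(self):
        rng = np.random.default_rng(2)
        arch = Architecture.make_linear(3)
        x = rng.normal(size=(10, 3))
        data = Dataset(x, rng.normal(size=10))
        w = rng.normal(size=3)
        alpha, beta = 0.7, 1.3
        h = gauss_newton_hessian(-x, alpha, beta)
        eps = 1e-5
        hfd = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                def f(wi, wj):
                    ww = w.copy()
                    ww[i] += wi
                    ww[j] += wj
                    return objective(arch, ww, data, alpha, beta)[0]

                hfd[i, j] = (
                    f(eps, eps) - f(eps, -eps) - f(-eps, eps) + f(-eps, -eps)
                ) / (4 * eps**2)
        assert np.abs(h - hfd).max() / np.abs(hfd).max() < 1e-6

    def test_nonfinite_jacobian_rejected(self):
        bad = np.full((2, 2), np.nan)
        with pytest.raises(TrainingError):
            gauss_newton_hessian(bad, 1.0, 1.0)


class TestLMStep:
    def test_single_step_reaches_ridge_minimizer(self, linear_problem):
        x, t = linear_problem
        arch = Architecture.make_linear(x.shape[1])
        alpha, beta = 0.5, 2.0
        w0 = np.zeros(x.shape[1])
        w1, accepted, _ = lm_step(
            arch, w0, Dataset(x, t), alpha, beta, damping=1e-12
        )
        assert accepted
        expected = ridge_solution(x, t, alpha / beta)
        assert np.abs(w1 - expected).max() < 1e-8

    def test_zero_gradient_stays_put(self, linear_problem):
        x, t = linear_problem
        arch = Architecture.make_linear(x.shape[1])
        alpha, beta = 0.5, 2.0
        w_star = ridge_solution(x, t, alpha / beta)
        w1, accepted, _ = lm_step(
            arch, w_star, Dataset(x, t), alpha, beta, damping=1e-6
        )
        assert accepted
        assert np.abs(w1 - w_star).max() < 1e-10

    def test_huge_damping_gives_gradient_descent_limit(self, linear_problem):
        x, t = linear_problem
        arch = Architecture.make_linear(x.shape[1])
        data = Dataset(x, t)
        w = np.zeros(x.shape[1])
        lam = 1e9
        g = gradient(arch, w, data, 1.0, 1.0)
        w1, accepted, _ = lm_step(arch, w, data, 1.0, 1.0, damping=lam)
        assert accepted
        np.testing.assert_allclose(w1 - w, -g / lam, rtol=1e-3)

    def test_never_increases_objective(self, linear_problem):
        x, t = linear_problem
        arch = Architecture.make_linear(x.shape[1])
        data = Dataset(x, t)
        rng = np.random.default_rng(3)
        w = rng.normal(size=x.shape[1]) * 10
        f = objective(arch, w, data, 1.0, 1.0)[0]
        for _ in range(5):
            w, accepted, _ = lm_step(arch, w, data, 1.0, 1.0, damping=1e-3)
            f_new = objective(arch, w, data, 1.0, 1.0)[0]
            assert f_new <= f + 1e-12
            f = f_new


class TestEffectiveParameters:
    def test_ridge_effective_degrees_of_freedom(self, linear_problem):
        x, t = linear_problem
        m = x.shape[1]
        alpha, beta = 0.8, 1.7
        h = gauss_newton_hessian(-x, alpha, beta)
        gamma = effective_parameters(alpha, h)
        eig = np.linalg.eigvalsh(x.T @ x)
        edf = np.sum(eig / (eig + alpha / beta))
        assert abs(gamma - edf) < 1e-8

    def test_alpha_to_zero_gives_m(self, linear_problem):
        x, _ = linear_problem
        m = x.shape[1]
        h = gauss_newton_hessian(-x, 1e-12, 1.0)
        assert effective_parameters(1e-12, h) == pytest.approx(m, abs=1e-6)

    def test_no_data_information_gives_zero(self):
        h = gauss_newton_hessian(np.zeros((4, 3)), alpha=2.0, beta=1.0)
        assert effective_parameters(2.0, h) == pytest.approx(0.0, abs=1e-12)

    def test_singular_hessian_raises(self):
        with pytest.raises(TrainingError):
            effective_parameters(0.0, np.zeros((2, 2)))


class TestUpdateAlphaBeta:
    def make_state(self, alpha, e_d, tr_hinv):
        return RegularizationState(
            alpha=alpha, beta=1.0, gamma=np.nan, e_d=e_d, e_w=np.nan,
            trace_hinv=tr_hinv,
        )

    def test_printed_formula_arithmetic(self):
        # w'w = 4, tr(H⁻¹) = 1, m = 10  ->  alpha_new = 10 / (2·5) = 1
        state = self.make_state(alpha=0.1, e_d=2.0, tr_hinv=1.0)
        w = np.array([2.0, 0.0, 0.0])
        alpha_new, _ = update_alpha_beta(state, w, n=100, m=10)
        assert alpha_new == pytest.approx(1.0)

    def test_beta_numerator_equals_n_minus_gamma(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            alpha = float(rng.uniform(0.1, 5))
            tr = float(rng.uniform(0.1, 3))
            m = int(rng.integers(5, 20))
            gamma = m - 2 * alpha * tr
            lhs = m - 2 * alpha * tr  # printed numerator n - m + 2α·trH⁻¹ ≡ n - γ
            assert abs((100 - m + 2 * alpha * tr) - (100 - gamma)) < 1e-12

    def test_overfit_guard(self):
        state = self.make_state(alpha=0.0, e_d=1.0, tr_hinv=0.0)
        with pytest.raises(TrainingError, match="exceed sample size"):
            update_alpha_beta(state, np.ones(3), n=5, m=10)

    def test_perfect_fit_guard(self):
        state = self.make_state(alpha=1.0, e_d=0.0, tr_hinv=0.1)
        with pytest.raises(TrainingError, match="perfect fit"):
            update_alpha_beta(state, np.ones(3), n=100, m=5)

    def test_mackay_and_printed_share_fixed_point(self):
        # at a self-consistent state both rules return the same alpha
        alpha, tr = 1.3, 0.4
        m = 8
        gamma = m - 2 * alpha * tr
        ww = gamma / (2 * alpha)  # fixed-point condition alpha = γ/(2E_W)
        w = np.zeros(m)
        w[0] = np.sqrt(ww)
        state = self.make_state(alpha=alpha, e_d=3.0, tr_hinv=tr)
        a_paper, _ = update_alpha_beta(state, w, n=50, m=m, rule="paper")
        a_mackay, _ = update_alpha_beta(state, w, n=50, m=m, rule="mackay")
        assert a_paper == pytest.approx(alpha, rel=1e-12)
        assert a_mackay == pytest.approx(alpha, rel=1e-12)


class TestLogEvidence:
    def test_matches_exact_gaussian_marginal_up_to_constant(self, linear_problem):
        x, t = linear_problem
        n, m = x.shape
        arch = Architecture.make_linear(m)
        data = Dataset(x, t)
        diffs = []
        for alpha in np.logspace(-2, 1, 4):
            for beta in np.logspace(-1, 1, 4):
                w_map = ridge_solution(x, t, alpha / beta)
                state, _ = _state_at(arch, w_map, data, alpha, beta)
                lap = log_evidence(state, n, m)
                exact = linear_log_marginal(x, t, alpha, beta)
                diffs.append(lap - exact)
        assert np.std(diffs) < 1e-8

    def test_pure_function_of_state(self, linear_problem):
        x, t = linear_problem
        arch = Architecture.make_linear(x.shape[1])
        data = Dataset(x, t)
        w = ridge_solution(x, t, 1.0)
        s1, _ = _state_at(arch, w, data, 1.0, 1.0)
        s2, _ = _state_at(arch, w, data, 1.0, 1.0)
        assert log_evidence(s1, *x.shape) == log_evidence(s2, *x.shape)


class TestHeritability:
    @pytest.mark.parametrize(
        "alpha, beta, expected", [(1.0, 1.0, 0.5), (3.0, 1.0, 0.25)]
    )
    def test_values(self, alpha, beta, expected):
        assert heritability(alpha, beta) == pytest.approx(expected)

    def test_alpha_to_zero_limit(self):
        assert heritability(1e-15, 1.0) == pytest.approx(1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)


class TestTrain:
    def test_linear_training_reaches_empirical_bayes_ridge(self, linear_problem):
        x, t = linear_problem
        arch = Architecture.make_linear(x.shape[1])
        net = train(arch, Dataset(x, t), TrainConfig(seed=1))
        alpha, beta = net.state.alpha, net.state.beta
        expected = ridge_solution(x, t, alpha / beta)
        assert np.abs(net.weights.flatten() - expected).max() < 1e-6
        eig = np.linalg.eigvalsh(x.T @ x)
        edf = np.sum(eig / (eig + alpha / beta))
        assert abs(net.state.gamma - edf) < 1e-8

    def test_pure_noise_shrinks_to_nothing(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(120, 20))
        t = rng.normal(size=120)
        t -= t.mean()
        arch = Architecture.make_linear(20)
        net = train(arch, Dataset(x, t), TrainConfig(seed=2))
        assert net.state.gamma < 0.1 * arch.n_weights
        preds = forward(arch, net.weights, x)
        assert np.std(preds) < 0.25 * np.std(t)

    def test_zero_epochs_returns_initialization(self):
        rng = np.random.default_rng(0)
        arch = Architecture(3, 2)
        data = Dataset(rng.normal(size=(10, 3)), rng.normal(size=10))
        cfg = TrainConfig(max_epochs=0, seed=5)
        net = train(arch, data, cfg)
        from brann.regularize import initialize_weights

        np.testing.assert_array_equal(
            net.weights.flatten(), initialize_weights(arch, cfg)
        )

    def test_bit_reproducible(self, linear_problem):
        x, t = linear_problem
        arch = Architecture.make_linear(x.shape[1])
        a = train(arch, Dataset(x, t), TrainConfig(seed=9))
        b = train(arch, Dataset(x, t), TrainConfig(seed=9))
        np.testing.assert_array_equal(a.weights.flatten(), b.weights.flatten())
        assert a.state.alpha == b.state.alpha

    def test_objective_monotone_with_fixed_hyperparameters(self):
        rng = np.random.default_rng(12)
        arch = Architecture(4, 2)
        data = Dataset(rng.normal(size=(30, 4)), rng.normal(size=30))
        cfg = TrainConfig(
            max_epochs=60, update_cadence=0, alpha_init=0.5, beta_init=2.0, seed=3
        )
        net = train(arch, data, cfg)
        f_vals = [h["F"] for h in net.history]
        assert all(b <= a + 1e-10 for a, b in zip(f_vals, f_vals[1:]))

    def test_gamma_within_bounds_every_epoch(self):
        rng = np.random.default_rng(13)
        arch = Architecture(5, 2)
        data = Dataset(rng.normal(size=(40, 5)), rng.normal(size=40))
        net = train(arch, data, TrainConfig(max_epochs=50, seed=4))
        m = arch.n_weights
        for h in net.history:
            assert -1e-6 <= h["gamma"] <= m + 1e-6

    def test_grid_argmax_agrees_with_fixed_point(self, linear_problem):
        # the iterative (α, β) fixed point maximizes the Laplace evidence:
        # a log-spaced grid around it finds no better cell than its own
        x, t = linear_problem
        n, m = x.shape
        arch = Architecture.make_linear(m)
        data = Dataset(x, t)
        net = train(arch, data, TrainConfig(seed=1))
        a_hat, b_hat = net.state.alpha, net.state.beta
        alphas = a_hat * np.logspace(-2, 2, 20)
        betas = b_hat * np.logspace(-2, 2, 20)
        best, best_ab = -np.inf, None
        for a in alphas:
            for b in betas:
                w_map = ridge_solution(x, t, a / b)
                state, _ = _state_at(arch, w_map, data, a, b)
                ev = log_evidence(state, n, m)
                if ev > best:
                    best, best_ab = ev, (a, b)
        step = np.log(alphas[1] / alphas[0])
        assert abs(np.log(best_ab[0] / a_hat)) <= step + 1e-9
        assert abs(np.log(best_ab[1] / b_hat)) <= step + 1e-9
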