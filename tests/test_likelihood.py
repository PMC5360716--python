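"""Gaussian map likelihood, nuisance conditionals and diagnostics."""

import numpy as np
import numpy.testing as npt
import pytest
from scipy.integrate import quad
from scipy.stats import truncnorm

from cryofit.maps import DensityMap
from cryofit.likelihood import (
    NuisanceState,
    map_energy,
    log_likelihood,
    cross_correlation,
    alpha_conditional,
    sample_alpha,
    lambda_conditional,
    sample_lambda,
    lambda_hat,
    marginal_log_likelihood,
    precision_diagnostics,
    lambda_profile_quadrature,
)


def tiny_map(values, mask=None):
    values = np.asarray(values, float).reshape(-1, 1, 1)
    m = None if mask is None else np.asarray(mask, bool).reshape(values.shape)
    return DensityMap(values, origin=[0, 0, 0], spacing=1.0, mask=m)


def test_nuisance_state_requires_positive():
    with pytest.raises(ValueError):
        NuisanceState(sigma=1.0, alpha=-0.1, lam=1.0)
    s = NuisanceState(sigma=2.25, alpha=1.0, lam=100.0)
    assert s.lam == 100.0


class TestMapEnergy:
    def test_perfect_masked_fit_is_zero(self):
        obs = tiny_map([2.0, 4.0, 6.0])
        assert map_energy(obs, obs.values / 2.0, 2.0) == 0.0

    def test_direct_sum(self):
        obs = tiny_map([1.0, 2.0])
        assert map_energy(obs, np.zeros_like(obs.values), 3.0) == pytest.approx(2.5)

    def test_matches_loop_oracle(self, small_obs, rng):
        model = rng.normal(size=small_obs.shape)
        alpha = 1.7
        naive = 0.5 * sum(
            (small_obs.values.ravel()[n] - alpha * model.ravel()[n]) ** 2
            for n in range(small_obs.n_voxels)
        )
        assert map_energy(small_obs, model, alpha) == pytest.approx(naive, abs=1e-12)

    def test_masked_voxels_do_not_contribute(self, rng):
        values = rng.normal(size=(4, 4, 4))
        model = rng.normal(size=(4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        obs = DensityMap(values, [0, 0, 0], 1.0, mask=mask)
        values2 = values.copy()
        values2[~mask] += 100.0  # arbitrary garbage outside the mask
        obs2 = DensityMap(values2, [0, 0, 0], 1.0, mask=mask)
        assert map_energy(obs, model, 1.1) == map_energy(obs2, model, 1.1)
        assert cross_correlation(obs, model) == cross_correlation(obs2, model)


class TestLogLikelihood:
    def test_perfect_fit_at_lambda_2pi(self):
        obs = tiny_map([1.0, 2.0, 3.0])
        assert log_likelihood(obs, obs.values, 1.0, 2.0 * np.pi) == pytest.approx(0.0)

    def test_lambda_doubling_algebra(self, small_obs, rng):
        model = rng.normal(size=small_obs.shape)
        lam = 0.8
        e = map_energy(small_obs, model, 1.0)
        n1 = small_obs.n_signal
        delta = log_likelihood(small_obs, model, 1.0, 2 * lam) - log_likelihood(
            small_obs, model, 1.0, lam
        )
        assert delta == pytest.approx(0.5 * n1 * np.log(2.0) - lam * e)

    def test_maximized_at_lambda_hat(self, small_obs, rng):
        model = rng.normal(size=small_obs.shape)
        lam_star = lambda_profile_quadrature(small_obs, model, 1.0)
        assert lam_star == pytest.approx(
            lambda_hat(small_obs, model, 1.0), rel=1e-5
        )

    def test_sufficient_statistic_identity(self, small_obs, rng):
        # -log likelihood decomposes exactly through E_map
        model = rng.normal(size=small_obs.shape)
        alpha, lam = 1.3, 2.1
        lhs = -log_likelihood(small_obs, model, alpha, lam)
        rhs = -0.5 * small_obs.n_signal * np.log(lam / (2 * np.pi)) + lam * map_energy(
            small_obs, model, alpha
        )
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestCrossCorrelation:
    def test_self_correlation_is_one(self, small_obs):
        assert cross_correlation(small_obs, small_obs.values) == pytest.approx(1.0)

    def test_scale_invariance(self, small_obs):
        assert cross_correlation(small_obs, 7.3 * small_obs.values) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        obs = tiny_map(rng.normal(size=20))
        model = rng.normal(size=obs.shape)
        y, f = obs.values.ravel(), model.ravel()
        naive = sum(a * b for a, b in zip(y, f)) / (
            np.sqrt(sum(a * a for a in y)) * np.sqrt(sum(b * b for b in f))
        )
        assert cross_correlation(obs, model) == pytest.approx(naive, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation(tiny_map([1.0, 2.0]), np.zeros((2, 1, 1)))


class TestAlphaConditional:
    def test_exact_slope(self, rng):
        model = rng.normal(size=(3, 3, 3))
        obs = DensityMap(2.0 * model, [0, 0, 0], 1.0)
        mean, prec = alpha_conditional(obs, model, lam=1.5)
        assert mean == pytest.approx(2.0)
        assert prec == pytest.approx(1.5 * (model**2).sum())

    def test_orthogonal_gives_zero(self):
        obs = tiny_map([1.0, 0.0])
        model = np.array([0.0, 1.0]).reshape(2, 1, 1)
        mean, _ = alpha_conditional(obs, model, 1.0)
        assert mean == pytest.approx(0.0)

    def test_matches_normal_equation_oracle(self, small_obs, rng):
        model = rng.normal(size=small_obs.shape)
        mean, _ = alpha_conditional(small_obs, model, 1.0)
        slope = np.linalg.lstsq(
            model.reshape(-1, 1), small_obs.values.ravel(), rcond=None
        )[0][0]
        assert mean == pytest.approx(slope, abs=1e-12)

    def test_zero_model_rejected(self, small_obs):
        with pytest.raises(ValueError, match="overlap"):
            alpha_conditional(small_obs, np.zeros(small_obs.shape), 1.0)


class TestSampleAlpha:
    def test_truncated_moments(self):
        rng = np.random.default_rng(7)
        mean, sd = -0.5, 1.0  # substantial truncation
        draws = np.array(
            [sample_alpha((mean, sd**-2), rng) for _ in range(100_000)]
        )
        assert (draws > 0).all()
        a = -mean / sd
        tn = truncnorm(a, np.inf, loc=mean, scale=sd)
        se = tn.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - tn.mean()) < 4 * se

    def test_zero_variance_limit(self):
        rng = np.random.default_rng(0)
        assert sample_alpha((3.0, 1e18), rng) == pytest.approx(3.0, abs=1e-6)

    def test_deterministic_under_seed(self):
        a = [sample_alpha((1.0, 4.0), np.random.default_rng(42)) for _ in range(3)]
        b = [sample_alpha((1.0, 4.0), np.random.default_rng(42)) for _ in range(3)]
        assert a == b

    def test_pathological_conditional_falls_back(self):
        rng = np.random.default_rng(1)
        draw = sample_alpha((-50.0, 100.0), rng)  # mean << 0, tiny variance
        assert draw > 0


class TestLambdaConditional:
    def test_shape_rate_from_mask_and_energy(self):
        obs = tiny_map(np.ones(10))
        model = np.zeros(obs.shape)
        model.ravel()[:] = [1.0] * 5 + [0.0] * 5
        e = map_energy(obs, model, 1.0)  # 0.5 * 5 = 2.5
        shape, rate = lambda_conditional(obs, model, 1.0)
        assert (shape, rate) == (5.0, pytest.approx(2.5))
        assert shape / rate == pytest.approx(lambda_hat(obs, model, 1.0))
        assert shape / rate == pytest.approx(2.0)

    def test_gamma_draw_moments(self):
        rng = np.random.default_rng(11)
        shape, rate = 5.0, 2.5
        draws = np.array([sample_lambda((shape, rate), rng) for _ in range(100_000)])
        mean, var = shape / rate, shape / rate**2
        se_mean = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 4 * se_mean
        se_var = var * np.sqrt(2.0 / (draws.size - 1)) * 2  # loose gamma bound
        assert abs(draws.var() - var) < 4 * se_var

    def test_perfect_fit_degenerate(self, small_obs):
        with pytest.raises(ValueError):
            lambda_conditional(small_obs, small_obs.values, 1.0)


class TestLambdaHat:
    def test_value(self):
        obs = tiny_map(np.ones(100))
        model = np.ones(obs.shape)
        obs.values[:] = model + 1.0  # residual 1 per voxel, E = 50
        assert lambda_hat(obs, model, 1.0) == pytest.approx(1.0)

    def test_zero_error_voxels_inflate(self):
        # appending perfectly fit voxels doubles N1 but leaves E_map alone
        y = np.array([1.0, 2.0, 3.0, 4.0])
        f = y + np.array([0.5, -0.5, 0.5, -0.5])
        small = tiny_map(y)
        lam_small = lambda_hat(small, f.reshape(-1, 1, 1), 1.0)
        y2 = np.concatenate([y, [5.0] * 4])
        f2 = np.concatenate([f, [5.0] * 4])
        big = tiny_map(y2)
        lam_big = lambda_hat(big, f2.reshape(-1, 1, 1), 1.0)
        assert lam_big == pytest.approx(2.0 * lam_small)


class TestMarginalLikelihood:
    def test_matches_quadrature_oracle(self, rng):
        obs = tiny_map(rng.normal(1.0, 0.5, size=10))
        model = np.abs(rng.normal(1.0, 0.5, size=obs.shape))
        lam = 2.3

        def integrand(alpha):
            return np.exp(log_likelihood(obs, model, alpha, lam))

        # integrate a window wide enough to hold all the Gaussian mass
        mean, prec = alpha_conditional(obs, model, lam)
        w = 15.0 * prec**-0.5
        integral, _ = quad(integrand, mean - w, mean + w, limit=200)
        ours = marginal_log_likelihood(obs, model, lam)
        assert ours == pytest.approx(np.log(integral), rel=1e-6)

    def test_maximal_at_perfect_correlation(self, rng):
        obs = tiny_map(np.abs(rng.normal(1, 0.3, size=12)))
        aligned = marginal_log_likelihood(obs, 0.5 * obs.values, 1.0)
        other = marginal_log_likelihood(
            obs, np.abs(rng.normal(1, 0.3, size=obs.shape)), 1.0
        )
        assert aligned > other

    def test_model_rescaling_shifts_by_log_c(self, small_obs, rng):
        # the theta-dependent part is scale-free (it enters only through C);
        # the exact alpha integral carries a 1/c Jacobian for model -> c*model
        model = rng.normal(size=small_obs.shape)
        c = 3.7
        base = marginal_log_likelihood(small_obs, model, 1.4)
        scaled = marginal_log_likelihood(small_obs, c * model, 1.4)
        assert scaled == pytest.approx(base - np.log(c), abs=1e-10)


class TestPrecisionDiagnostics:
    def test_recovers_known_precision(self, rng):
        lam_star = 50.0
        model = rng.uniform(0.5, 1.5, size=(25, 25, 25))
        obs = DensityMap(
            model + rng.normal(0, lam_star**-0.5, size=model.shape), [0, 0, 0], 1.0
        )
        report = precision_diagnostics([("masked", obs, model)], alpha=1.0)
        lam = report["lambda_hat"].iloc[0]
        assert abs(lam - lam_star) / lam_star < 0.1
        assert report["count"].sum() == obs.n_voxels

    def test_zero_padding_raises_precision(self, rng):
        model = rng.uniform(0.5, 1.5, size=(6, 6, 6))
        obs_vals = model + rng.normal(0, 0.2, size=model.shape)
        plain = DensityMap(obs_vals, [0, 0, 0], 1.0)
        padded_vals = np.zeros((8, 8, 8))
        padded_vals[1:7, 1:7, 1:7] = obs_vals
        padded_model = np.zeros((8, 8, 8))
        padded_model[1:7, 1:7, 1:7] = model
        padded = DensityMap(padded_vals, [0, 0, 0], 1.0)
        report = precision_diagnostics(
            [("plain", plain, model), ("padded", padded, padded_model)]
        )
        by_stage = report.groupby("stage")["lambda_hat"].first()
        assert by_stage["padded"] > by_stage["plain"]
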