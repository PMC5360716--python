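"""HMC, Gibbs sweeps and replica exchange."""

import numpy as np
import numpy.testing as npt
import pytest
from scipy.integrate import dblquad

from cryofit.maps import DensityMap
from cryofit.samplers import (
    hmc_step,
    build_schedule,
    replica_exchange,
    gibbs_sweep,
    SamplerState,
)
from cryofit.likelihood import NuisanceState
from cryofit.posterior import FitProblem, CartesianModel


def gaussian_2d_energy(cov):
    prec = np.linalg.inv(cov)

    def energy(x):
        return 0.5 * float(x @ prec @ x), prec @ x

    return energy


class TestHMC:
    def test_recovers_gaussian_moments(self):
        cov = np.array([[2.0, 0.6], [0.6, 0.5]])
        energy = gaussian_2d_energy(cov)
        rng = np.random.default_rng(1)
        x = np.zeros(2)
        samples = []
        for _ in range(20_000):
            x = hmc_step(x, energy, rng, n_leapfrog=5, step_size=0.5).x
            samples.append(x)
        s = np.array(samples[2000:])
        n = s.shape[0]
        for d in range(2):
            se = np.sqrt(cov[d, d] / n) * 3  # inflate for autocorrelation
            assert abs(s[:, d].mean()) < 4 * se
        emp_cov = np.cov(s.T)
        assert np.abs(emp_cov - cov).max() < 0.15

    def test_delta_h_scales_quadratically(self):
        energy = gaussian_2d_energy(np.eye(2))

        def mean_abs_dh(step):
            rng = np.random.default_rng(2)
            vals = []
            for _ in range(300):
                r = hmc_step(
                    np.array([1.0, 0.5]), energy, rng,
                    n_leapfrog=max(1, int(round(1.0 / step))), step_size=step,
                )
                vals.append(abs(r.delta_h))
            return np.mean(vals)

        d1, d2 = mean_abs_dh(0.1), mean_abs_dh(0.01)
        ratio = d1 / d2
        assert 50 < ratio < 200  # one decade in step -> two decades in |dH|

    def test_near_perfect_acceptance_with_tiny_step(self):
        energy = gaussian_2d_energy(np.eye(2))
        rng = np.random.default_rng(3)
        acc = [
            hmc_step(rng.normal(size=2), energy, rng, n_leapfrog=10, step_size=0.01).accepted
            for _ in range(200)
        ]
        assert np.mean(acc) > 0.99

    def test_nonfinite_energy_rejects(self):
        def bad_energy(x):
            if abs(x[0]) > 0.5:
                return np.inf, np.full_like(x, np.nan)
            return 0.0, np.zeros_like(x)

        rng = np.random.default_rng(4)
        r = hmc_step(np.array([0.4]), bad_energy, rng, n_leapfrog=5, step_size=1.0)
        assert not r.accepted
        npt.assert_array_equal(r.x, [0.4])

    def test_reproducible_under_seed(self):
        energy = gaussian_2d_energy(np.eye(2))

        def run():
            rng = np.random.default_rng(99)
            x = np.zeros(2)
            for _ in range(50):
                x = hmc_step(x, energy, rng, 5, 0.3).x
            return x

        npt.assert_array_equal(run(), run())

    def test_detailed_balance_on_discretized_chain(self):
        # bin a long 1-D HMC chain; the empirical transition flow between
        # bins must be symmetric under the stationary distribution
        def energy(x):
            return 0.5 * float(x @ x), x

        rng = np.random.default_rng(5)
        x = np.zeros(1)
        xs = []
        for _ in range(40_000):
            x = hmc_step(x, energy, rng, 3, 0.6).x
            xs.append(x[0])
        xs = np.array(xs)
        bins = np.digitize(xs, [-0.5, 0.5])  # three coarse states
        counts = np.zeros((3, 3))
        for a, b in zip(bins[:-1], bins[1:]):
            counts[a, b] += 1
        flow = counts / counts.sum()
        assert np.abs(flow - flow.T).max() < 0.01


class TestSchedule:
    def test_single_replica(self):
        s = build_schedule(1)
        npt.assert_array_equal(s.betas, [1.0])
        npt.assert_array_equal(s.qs, [1.0])

    def test_endpoints_and_monotonicity(self):
        s = build_schedule(6, beta_min=0.02, q_max=1.4)
        assert (s.betas[0], s.qs[0]) == (1.0, 1.0)
        assert (s.betas[-1], s.qs[-1]) == (0.02, 1.4)
        assert np.all(np.diff(s.betas) < 0)
        assert np.all(np.diff(s.qs) > 0)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            build_schedule(3, beta_min=0.0)
        with pytest.raises(ValueError):
            build_schedule(3, q_max=0.5)
        with pytest.raises(ValueError):
            build_schedule(0)


class TestReplicaExchange:
    def test_identical_neighbors_always_swap(self):
        fns = [lambda x: float(x @ x)] * 3
        rng = np.random.default_rng(6)

        def step(i, x, r):
            return x + r.normal(0, 0.1, size=x.shape)

        _, stats = replica_exchange(fns, [np.zeros(2)] * 3, step, rng, 50)
        assert stats["swap_rates"].min() == 1.0

    def test_two_state_stationary_distribution(self):
        # discrete two-state target at two rungs; exact stationary occupancy
        # of the cold rung is exp(-E)/Z
        e_cold = np.array([0.0, 2.0])
        e_hot = np.array([0.0, 0.2])
        energies = [e_cold, e_hot]
        fns = [lambda x, e=e: float(e[int(x[0])]) for e in energies]

        def step(i, x, r):
            prop = np.array([1.0 - x[0]])
            de = energies[i][int(prop[0])] - energies[i][int(x[0])]
            if de <= 0 or r.uniform() < np.exp(-de):
                return prop
            return x

        rng = np.random.default_rng(7)
        samples, _ = replica_exchange(fns, [np.zeros(1), np.zeros(1)], step, rng, 60_000)
        occ = np.mean([s[0] for s in samples[5000:]])
        target = np.exp(-2.0) / (1.0 + np.exp(-2.0))
        assert abs(occ - target) < 0.01

    def test_double_well_mixing_beats_single_chain(self):
        # barrier height ~16: a cold random-walk chain stays in its well,
        # replica exchange equilibrates both wells
        def well(beta):
            return lambda x: beta * 16.0 * float((x[0] ** 2 - 1.0) ** 2)

        fns = [well(b) for b in (1.0, 0.3, 0.1, 0.02)]

        def step(i, x, r):
            prop = x + r.normal(0, 0.3, size=x.shape)
            if np.log(r.uniform()) < fns[i](x) - fns[i](prop):
                return prop
            return x

        rng = np.random.default_rng(8)
        samples, stats = replica_exchange(
            fns, [np.array([-1.0])] * 4, step, rng, 20_000, swap_stride=5
        )
        occ_right = np.mean([s[0] > 0 for s in samples[2000:]])
        assert abs(occ_right - 0.5) < 0.1

        # matched-budget single chain cannot cross
        x = np.array([-1.0])
        crossed = 0
        for _ in range(20_000):
            x = step(0, x, rng)
            crossed += x[0] > 0
        assert crossed / 20_000 < 0.05

    def test_swaps_preserve_target_marginal(self):
        # with and without swaps, the cold-rung marginal of a harmonic
        # target agrees within MC error
        def harm(beta):
            return lambda x: beta * 0.5 * float(x @ x)

        fns = [harm(b) for b in (1.0, 0.25)]

        def step(i, x, r):
            prop = x + r.normal(0, 0.8, size=x.shape)
            if np.log(r.uniform()) < fns[i](x) - fns[i](prop):
                return prop
            return x

        out = {}
        for stride, label in [(1, "with"), (10**9, "without")]:
            rng = np.random.default_rng(9)
            samples, _ = replica_exchange(
                fns, [np.zeros(1)] * 2, step, rng, 30_000, swap_stride=stride
            )
            out[label] = np.array([s[0] for s in samples[3000:]])
        assert abs(out["with"].var() - 1.0) < 0.05
        assert abs(out["without"].var() - 1.0) < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            replica_exchange([lambda x: 0.0], [], lambda i, x, r: x, np.random.default_rng(0), 1)


@pytest.fixture(scope="module")
def conjugate_problem():
    # tiny fixed-theta problem: obs = alpha* model + noise
    rng = np.random.default_rng(10)
    model_vals = rng.uniform(0.5, 1.5, size=(4, 4, 4))
    obs = DensityMap(
        2.0 * model_vals + rng.normal(0, 0.2, size=model_vals.shape),
        [0, 0, 0],
        1.0,
    )

    class FrozenModel:
        n_dof = 3

        def coords(self, flat):
            return np.zeros((1, 3))

        def gradient(self, flat, cart):
            return np.zeros(3)

    problem = FitProblem(obs=obs, model=FrozenModel(), sigma=1.0)

    # patch rendering so theta is inert and the conditionals are exact
    problem.model_values = lambda flat, sigma=None: model_vals
    return problem, obs, model_vals


class TestGibbs:

    def test_nuisance_chain_matches_quadrature(self, conjugate_problem):
        problem, obs, model_vals = conjugate_problem
        rng = np.random.default_rng(11)
        state = SamplerState(
            dof=np.zeros(3), nuisance=NuisanceState(1.0, 1.0, 1.0)
        )
        alphas, lams = [], []
        for _ in range(4000):
            state, _ = gibbs_sweep(
                state, problem, rng, n_leapfrog=0, step_size=0.0
            )
            alphas.append(state.nuisance.alpha)
            lams.append(state.nuisance.lam)
        alphas, lams = np.array(alphas[500:]), np.array(lams[500:])

        # oracle: joint posterior ~ N x Gamma via 2-D quadrature
        y = obs.values.ravel()
        f = model_vals.ravel()
        n1 = y.size

        def unnorm(alpha, lam):
            e = 0.5 * ((y - alpha * f) ** 2).sum()
            return lam ** (n1 / 2 - 1) * np.exp(-lam * e)

        # dblquad integrates f(y, x): alpha is the inner variable, lam outer
        z, _ = dblquad(unnorm, 8, 60, 1.8, 2.2)
        za, _ = dblquad(lambda a, l: unnorm(a, l) * a, 8, 60, 1.8, 2.2)
        zl, _ = dblquad(lambda a, l: unnorm(a, l) * l, 8, 60, 1.8, 2.2)
        mean_alpha, mean_lam = za / z, zl / z
        assert abs(alphas.mean() - mean_alpha) < 0.02
        assert abs(lams.mean() - mean_lam) / mean_lam < 0.05

    def test_lambda_trace_tracks_inverse_mse(self, conjugate_problem):
        problem, obs, model_vals = conjugate_problem
        rng = np.random.default_rng(12)
        state = SamplerState(dof=np.zeros(3), nuisance=NuisanceState(1.0, 1.0, 1.0))
        lams = []
        for _ in range(2000):
            state, _ = gibbs_sweep(state, problem, rng, n_leapfrog=0, step_size=0.0)
            lams.append(state.nuisance.lam)
        from cryofit.likelihood import lambda_hat, alpha_conditional

        alpha_hat = alpha_conditional(obs, model_vals, 1.0)[0]
        expected = lambda_hat(obs, model_vals, alpha_hat)
        assert abs(np.mean(lams[200:]) - expected) / expected < 0.1

    def test_fixed_seed_reproducible(self, conjugate_problem):
        problem, _, _ = conjugate_problem

        def run():
            rng = np.random.default_rng(13)
            state = SamplerState(dof=np.zeros(3), nuisance=NuisanceState(1.0, 1.0, 1.0))
            out = []
            for _ in range(20):
                state, _ = gibbs_sweep(state, problem, rng, 0, 0.0)
                out.append((state.nuisance.alpha, state.nuisance.lam))
            return out

        assert run() == run()
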