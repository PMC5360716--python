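"""Posterior simulation: Hamiltonian Monte Carlo, Gibbs sweeps over
structure and nuisance parameters, and replica exchange on a (beta, q)
ladder.

The Gibbs scheme alternates

    theta ~ Pr(theta | xi, D)      (one HMC update of the conformation)
    alpha ~ Pr(alpha | lambda, theta, D)   (truncated Gaussian)
    lambda ~ Pr(lambda | alpha, theta, D)  (Gamma)

HMC proposes a new conformation by integrating Hamiltonian dynamics of the
hybrid energy (negative log posterior over theta) with the leapfrog scheme
and accepting with probability min(1, exp(-delta H)); momenta are drawn
fresh from a Gaussian each step and discarded afterwards.

Replica exchange runs one chain per rung of a ladder of tempered posteriors
parameterized by (beta, q): beta in [0, 1] raises the likelihood to a
power, q >= 1 flattens the non-bonded prior through the Tsallis
transformation.  Rung 0 is always the target (beta=1, q=1).  Neighbor swaps
use the standard Metropolis criterion on the cross-evaluated tempered
energies, which preserves the product stationary distribution for any
ladder; even/odd pairs are alternated deterministically.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from cryofit.likelihood import (
    alpha_conditional,
    lambda_conditional,
    sample_alpha,
    sample_lambda,
    NuisanceState,
)

__all__ = [
    "HMCResult",
    "hmc_step",
    "ReplicaSchedule",
    "build_schedule",
    "replica_exchange",
    "gibbs_sweep",
    "SamplerState",
]

EnergyFn = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclasses.dataclass
class HMCResult:
    x: np.ndarray
    accepted: bool
    delta_h: float
    energy: float


def hmc_step(
    x: np.ndarray,
    energy_fn: EnergyFn,
    rng: np.random.Generator,
    n_leapfrog: int = 10,
    step_size: float = 0.1,
    masses: np.ndarray | float = 1.0,
) -> HMCResult:
    """One Hamiltonian Monte Carlo update of a flat coordinate vector.

    ``energy_fn`` returns the scalar energy (negative log density) and its
    gradient.  Momenta are Gaussian with the given (diagonal) masses.  A
    non-finite energy or gradient along the trajectory rejects the proposal
    outright.
    """
    x = np.asarray(x, dtype=np.float64)
    if n_leapfrog < 1:  # degenerate no-op update (used to freeze theta)
        return HMCResult(x.copy(), True, 0.0, np.nan)
    masses = np.broadcast_to(np.asarray(masses, dtype=np.float64), x.shape)
    e0, g = energy_fn(x)
    p = rng.normal(size=x.shape) * np.sqrt(masses)
    h0 = e0 + 0.5 * float(p @ (p / masses))

    q = x.copy()
    p = p - 0.5 * step_size * g
    ok = True
    for step in range(n_leapfrog):
        q = q + step_size * p / masses
        e1, g = energy_fn(q)
        if not (np.isfinite(e1) and np.all(np.isfinite(g))):
            ok = False
            break
        p = p - step_size * g * (0.5 if step == n_leapfrog - 1 else 1.0)

    if not ok:
        return HMCResult(x, False, np.inf, e0)
    h1 = e1 + 0.5 * float(p @ (p / masses))
    dh = h1 - h0
    if dh <= 0 or rng.uniform() < np.exp(-dh):
        return HMCResult(q, True, dh, e1)
    return HMCResult(x, False, dh, e0)


@dataclasses.dataclass
class ReplicaSchedule:
    """Ladder of (beta, q) pairs; rung 0 is the target posterior (1, 1).

    beta is nonincreasing and q nondecreasing along the ladder.  E_min is
    the Tsallis reference energy shared by all rungs; ``swap_stride`` is
    the number of sweeps between swap attempts.
    """

    betas: np.ndarray
    qs: np.ndarray
    e_min: float = 0.0
    swap_stride: int = 1

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=np.float64)
        self.qs = np.asarray(self.qs, dtype=np.float64)
        if self.betas.shape != self.qs.shape or self.betas.ndim != 1:
            raise ValueError("betas and qs must be 1-D arrays of equal length")
        if not (self.betas[0] == 1.0 and self.qs[0] == 1.0):
            raise ValueError("rung 0 must be the target (beta=1, q=1)")
        if np.any(np.diff(self.betas) > 1e-12) or np.any(np.diff(self.qs) < -1e-12):
            raise ValueError("beta must be nonincreasing and q nondecreasing")
        if np.any(self.betas < 0) or np.any(self.betas > 1) or np.any(self.qs < 1):
            raise ValueError("require beta in [0, 1] and q >= 1")

    @property
    def n_replicas(self) -> int:
        return self.betas.size


def build_schedule(
    n_replicas: int,
    beta_min: float = 0.01,
    q_max: float = 1.1,
    e_min: float = 0.0,
    swap_stride: int = 1,
) -> ReplicaSchedule:
    """Geometric beta ladder from 1 down to ``beta_min`` and linear q
    ladder from 1 up to ``q_max``; a single replica gives [(1, 1)]."""
    if n_replicas < 1:
        raise ValueError("need at least one replica")
    if not (0 < beta_min <= 1) or q_max < 1:
        raise ValueError("require 0 < beta_min <= 1 and q_max >= 1")
    if n_replicas == 1:
        return ReplicaSchedule(np.array([1.0]), np.array([1.0]), e_min, swap_stride)
    i = np.arange(n_replicas)
    betas = beta_min ** (i / (n_replicas - 1))
    qs = 1.0 + (q_max - 1.0) * i / (n_replicas - 1)
    betas[0], qs[0] = 1.0, 1.0
    betas[-1], qs[-1] = beta_min, q_max
    return ReplicaSchedule(betas, qs, e_min, swap_stride)


def replica_exchange(
    energy_fns: Sequence[Callable[[np.ndarray], float]],
    initial: Sequence[np.ndarray],
    step_fn: Callable[[int, np.ndarray, np.random.Generator], np.ndarray],
    rng: np.random.Generator,
    n_sweeps: int,
    swap_stride: int = 1,
) -> tuple[list[np.ndarray], dict]:
    """Generic replica-exchange driver.

    ``energy_fns[i]`` evaluates the tempered energy of rung i (used only
    for swaps); ``step_fn(i, x, rng)`` performs the within-replica update
    at rung i.  Swaps of neighboring rungs are attempted every
    ``swap_stride`` sweeps, alternating even and odd pairs, with acceptance
    min(1, exp(-Delta)), Delta = U_i(x_j) + U_j(x_i) - U_i(x_i) - U_j(x_j).

    Returns samples collected from rung 0 after every sweep and a stats
    dict with per-pair attempt/accept counts.
    """
    n = len(energy_fns)
    if len(initial) != n:
        raise ValueError("one initial state per replica required")
    xs = [np.array(x, dtype=np.float64) for x in initial]
    samples: list[np.ndarray] = []
    attempts = np.zeros(max(n - 1, 1), dtype=int)
    accepts = np.zeros(max(n - 1, 1), dtype=int)
    parity = 0
    for sweep in range(n_sweeps):
        for i in range(n):
            xs[i] = step_fn(i, xs[i], rng)
        if n > 1 and (sweep + 1) % swap_stride == 0:
            for i in range(parity, n - 1, 2):
                j = i + 1
                uii = energy_fns[i](xs[i])
                ujj = energy_fns[j](xs[j])
                uij = energy_fns[i](xs[j])
                uji = energy_fns[j](xs[i])
                delta = (uij + uji) - (uii + ujj)
                attempts[i] += 1
                if delta <= 0 or rng.uniform() < np.exp(-delta):
                    xs[i], xs[j] = xs[j], xs[i]
                    accepts[i] += 1
            parity = 1 - parity
        samples.append(xs[0].copy())
    rates = np.divide(
        accepts, attempts, out=np.zeros_like(accepts, dtype=float), where=attempts > 0
    )
    stats = {
        "swap_attempts": attempts,
        "swap_accepts": accepts,
        "swap_rates": rates,
        "mean_swap_rate": float(rates[attempts > 0].mean()) if (attempts > 0).any() else np.nan,
    }
    return samples, stats


@dataclasses.dataclass
class SamplerState:
    """Current state of the Gibbs chain: conformation theta and nuisance xi.

    ``dof`` is the flat conformational vector; cached quantities (model
    map, E_map, prior energy) are recomputed whenever the dof change.
    """

    dof: np.ndarray
    nuisance: NuisanceState
    model_values: np.ndarray | None = None
    e_map: float | None = None
    e_prior: float | None = None
    iteration: int = 0


def gibbs_sweep(
    state: SamplerState,
    problem,
    rng: np.random.Generator,
    n_leapfrog: int = 10,
    step_size: float = 0.05,
    masses: np.ndarray | float = 1.0,
    beta: float = 1.0,
    q: float = 1.0,
    e_min: float = 0.0,
    update_sigma: bool = False,
    sigma_step: float = 0.05,
) -> tuple[SamplerState, HMCResult]:
    """One sweep of the Gibbs sampler for a map-fitting problem.

    First the conformation is updated with HMC at fixed nuisance
    parameters, then alpha and lambda are drawn from their exact (possibly
    tempered) conditionals in that order.  ``problem`` is a
    :class:`cryofit.posterior.FitProblem`.  With ``update_sigma`` a
    random-walk Metropolis step on log sigma is appended (off by default:
    the bandwidth is normally fixed by the map resolution).

    For beta = 0 the likelihood is switched off and the nuisance
    parameters are left unchanged (their tempered conditionals are
    improper).
    """
    nu = state.nuisance

    def energy(x: np.ndarray) -> tuple[float, np.ndarray]:
        return problem.tempered_energy_gradient(
            x, nu.alpha, nu.lam, nu.sigma, beta=beta, q=q, e_min=e_min
        )

    res = hmc_step(state.dof, energy, rng, n_leapfrog, step_size, masses)
    dof = res.x
    has_map = problem.obs is not None
    model = problem.model_values(dof, nu.sigma) if has_map else None

    alpha, lam = nu.alpha, nu.lam
    if has_map and beta > 1e-9:
        mean, prec = alpha_conditional(problem.obs, model, lam)
        alpha = sample_alpha((mean, beta * prec), rng)
        shape, rate = lambda_conditional(problem.obs, model, alpha)
        lam = sample_lambda((beta * shape, beta * rate), rng)
    sigma = nu.sigma
    if update_sigma and has_map and beta > 1e-9:
        from cryofit.likelihood import log_likelihood

        prop = sigma * np.exp(rng.normal(0.0, sigma_step))
        model_prop = problem.model_values(dof, prop)
        ll0 = log_likelihood(problem.obs, model, alpha, lam)
        ll1 = log_likelihood(problem.obs, model_prop, alpha, lam)
        if np.log(rng.uniform()) < beta * (ll1 - ll0):
            sigma, model = prop, model_prop

    new_nu = NuisanceState(sigma=sigma, alpha=alpha, lam=lam)
    from cryofit.likelihood import map_energy

    new_state = SamplerState(
        dof=dof,
        nuisance=new_nu,
        model_values=model,
        e_map=map_energy(problem.obs, model, alpha) if has_map else None,
        e_prior=problem.prior_energy(dof),
        iteration=state.iteration + 1,
    )
    return new_state, res
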