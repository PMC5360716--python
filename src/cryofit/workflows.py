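"""End-to-end fitting recipes and trajectory analysis.

Three fitting modes are provided on top of the sampling machinery:

* :func:`fit_flexible` — local HMC-within-Gibbs refinement of a single
  chain in torsion space against a map (no replica exchange): the standard
  flexible-fitting setting where the start structure is a known
  conformation and the map shows another.
* :func:`fit_rigid_symmetric` — replica-exchange sampling of the six rigid
  degrees of freedom of one subunit whose symmetry mates are generated
  virtually; supports prior-only (packing) mode — box plus force field and
  no map term — and full-posterior mode.
* :func:`fit_multibody` — joint rigid-body sampling of several subunits,
  optionally staged: a first pass with the non-bonded terms switched off
  to shortcut convergence, then refinement with the terms on.

Analysis helpers: :func:`rmsd` (raw or least-squares superposed) and
:func:`cluster_poses` (single-linkage clustering in pairwise-RMSD space
with per-cluster population, mean energy and ensemble RMSD).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from cryofit.maps import DensityMap
from cryofit.structures import Structure
from cryofit.likelihood import (
    NuisanceState,
    alpha_conditional,
    cross_correlation,
    lambda_hat,
)
from cryofit.priors import BoxPrior
from cryofit.posterior import FitProblem, RigidBodyModel, TorsionModel
from cryofit.dof import TorsionTopology, SymmetrySpec
from cryofit.samplers import (
    SamplerState,
    gibbs_sweep,
    build_schedule,
    replica_exchange,
    ReplicaSchedule,
)

__all__ = [
    "rmsd",
    "cluster_poses",
    "fit_flexible",
    "fit_rigid_symmetric",
    "fit_multibody",
    "FitResult",
]


def rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    selection: np.ndarray | None = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation between two coordinate sets (Å).

    With ``superpose`` the optimal least-squares rigid superposition
    (rotation + translation) is applied first; otherwise the raw deviation
    in the common frame is returned — the appropriate choice for
    assemblies, where the absolute pose matters.
    """
    a = np.asarray(coords_a, dtype=np.float64)
    b = np.asarray(coords_b, dtype=np.float64)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if superpose:
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        rot, _ = Rotation.align_vectors(a - ca, b - cb)
        b = (b - cb) @ rot.as_matrix().T + ca
    d = a - b
    return float(np.sqrt((d * d).sum() / a.shape[0]))


def cluster_poses(
    coord_sets: list[np.ndarray],
    linkage_cutoff: float = 1.0,
    energies: np.ndarray | None = None,
    superpose: bool = False,
) -> list[dict]:
    """Single-linkage clustering of sampled structures in RMSD space.

    Returns one dict per cluster, ordered by mean energy (or by population
    when no energies are given), with keys ``members``, ``population_pct``,
    ``mean_energy``, ``ensemble_rmsd`` (mean pairwise RMSD within the
    cluster) and ``representative`` (index of the lowest-energy member).
    Populations sum to 100%.
    """
    n = len(coord_sets)
    if n == 0:
        raise ValueError("no samples to cluster")
    if energies is not None:
        energies = np.asarray(energies, dtype=np.float64)
    if n == 1:
        return [
            {
                "members": np.array([0]),
                "population_pct": 100.0,
                "mean_energy": float(energies[0]) if energies is not None else np.nan,
                "ensemble_rmsd": 0.0,
                "representative": 0,
            }
        ]
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = rmsd(
                coord_sets[i], coord_sets[j], superpose=superpose
            )
    labels = fcluster(
        linkage(squareform(dmat, checks=False), method="single"),
        t=linkage_cutoff,
        criterion="distance",
    )
    clusters = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        sub = dmat[np.ix_(members, members)]
        ens = float(sub[np.triu_indices(len(members), 1)].mean()) if len(members) > 1 else 0.0
        e = float(energies[members].mean()) if energies is not None else np.nan
        rep = int(members[np.argmin(energies[members])]) if energies is not None else int(members[0])
        clusters.append(
            {
                "members": members,
                "population_pct": 100.0 * len(members) / n,
                "mean_energy": e,
                "ensemble_rmsd": ens,
                "representative": rep,
            }
        )
    if energies is not None:
        clusters.sort(key=lambda c: c["mean_energy"])
    else:
        clusters.sort(key=lambda c: -c["population_pct"])
    return clusters


@dataclasses.dataclass
class FitResult:
    """Output of a fitting workflow.

    trajectory : sampled model coordinate sets (full assembly frame);
    trace : per-iteration diagnostics; clusters : pose clusters (rigid
    workflows); final_coords : last sampled coordinates; stats : sampler
    statistics (swap rates etc.).
    """

    trajectory: list[np.ndarray]
    trace: pd.DataFrame
    final_coords: np.ndarray
    clusters: list[dict] | None = None
    stats: dict | None = None


def _init_nuisance(problem: FitProblem, flat: np.ndarray, sigma: float) -> NuisanceState:
    model = problem.model_values(flat, sigma)
    mean, _ = alpha_conditional(problem.obs, model, 1.0)
    alpha = max(mean, 1e-6)
    lam = lambda_hat(problem.obs, model, alpha)
    return NuisanceState(sigma=sigma, alpha=alpha, lam=lam)


def fit_flexible(
    structure: Structure,
    dmap: DensityMap,
    sigma: float,
    n_iterations: int = 100,
    n_leapfrog: int = 10,
    step_size: float = 0.01,
    target: Structure | None = None,
    domains: dict[str, np.ndarray] | None = None,
    include_rigid: bool = False,
    force_field: str | None = "quartic",
    radii: float = 1.8,
    force_constant: float = 1.0,
    seed: int = 0,
    adapt: bool = True,
) -> FitResult:
    """Local flexible fitting of one chain into a map, in torsion space.

    HMC-within-Gibbs from the given start structure; no replica exchange,
    so sampling stays in the basin of the start — the refinement setting.
    The trace records the cross-correlation, RMSD to the start, RMSD to
    the target (if given; superposed) and per-domain RMSD for any supplied
    domain index sets.  The step size is halved whenever the recent
    acceptance rate drops below 0.5 during the first half of the run
    (burn-in adaptation), then frozen.
    """
    rng = np.random.default_rng(seed)
    topo = TorsionTopology.from_structure(structure)
    model = TorsionModel(structure.coords, topo, include_rigid=include_rigid)
    exclude = {tuple(sorted(b)) for b in (structure.bonds or [])}
    problem = FitProblem(
        obs=dmap,
        model=model,
        sigma=sigma,
        force_field=force_field,
        radii=radii,
        force_constant=force_constant,
        exclude_pairs=exclude,
        box=None,
    )
    flat = np.zeros(model.n_dof)
    flat[-topo.n_torsions :] = topo.measure(structure.coords)
    state = SamplerState(dof=flat, nuisance=_init_nuisance(problem, flat, sigma))

    rows = []
    trajectory = []
    accept_window: list[bool] = []
    for it in range(n_iterations):
        state, res = gibbs_sweep(
            state, problem, rng, n_leapfrog=n_leapfrog, step_size=step_size
        )
        accept_window.append(res.accepted)
        if adapt and it < n_iterations // 2 and len(accept_window) >= 10:
            if np.mean(accept_window[-10:]) < 0.5:
                step_size *= 0.5
                accept_window.clear()
        coords = model.coords(state.dof)
        trajectory.append(coords)
        row = {
            "iteration": it,
            "cross_correlation": cross_correlation(dmap, state.model_values),
            "rmsd_to_start": rmsd(coords, structure.coords, superpose=True),
            "alpha": state.nuisance.alpha,
            "lambda": state.nuisance.lam,
            "e_map": state.e_map,
            "e_prior": state.e_prior,
            "accepted": res.accepted,
            "step_size": step_size,
        }
        if target is not None:
            row["rmsd_to_target"] = rmsd(coords, target.coords, superpose=True)
            if domains:
                for name, idx in domains.items():
                    row[f"rmsd_{name}"] = rmsd(
                        coords, target.coords, selection=idx, superpose=True
                    )
        rows.append(row)
    return FitResult(
        trajectory=trajectory,
        trace=pd.DataFrame(rows),
        final_coords=trajectory[-1],
    )


def _replica_fit(
    problem: FitProblem,
    schedule: ReplicaSchedule,
    init_flat: np.ndarray,
    sigma: float,
    n_sweeps: int,
    rng: np.random.Generator,
    n_leapfrog: int = 10,
    step_size: float = 0.05,
    jitter: float = 0.0,
) -> tuple[list[np.ndarray], dict, list[NuisanceState]]:
    """Replica-exchange Gibbs sampling of a fit problem.

    Each rung keeps its own nuisance state (sampled from tempered
    conditionals); swaps exchange conformations only.  ``jitter`` spreads
    the initial conformations of the hotter rungs.  Per-replica HMC step
    sizes are adapted multiplicatively during the first half of the run
    (grown on acceptance, shrunk on rejection, targeting the usual 60-90%
    acceptance window) and frozen afterwards so the stationary
    distribution is preserved.
    """
    n = schedule.n_replicas
    has_map = problem.obs is not None
    if has_map:
        nuisances = [_init_nuisance(problem, init_flat, sigma) for _ in range(n)]
    else:
        nuisances = [NuisanceState(sigma, 1.0, 1.0) for _ in range(n)]
    initial = [
        np.asarray(init_flat, dtype=np.float64)
        + (jitter * i / max(n - 1, 1)) * rng.normal(size=np.size(init_flat))
        for i in range(n)
    ]

    def energy_fn(i):
        def fn(x):
            nu = nuisances[i]
            return problem.tempered_energy(
                x, nu.alpha, nu.lam, nu.sigma,
                beta=schedule.betas[i] if has_map else 0.0,
                q=schedule.qs[i], e_min=schedule.e_min,
            )
        return fn

    steps = [step_size] * n
    sweep_count = [0] * n
    adapt_until = max(n_sweeps // 2, 1)

    def step_fn(i, x, step_rng):
        state = SamplerState(dof=x, nuisance=nuisances[i])
        new_state, res = gibbs_sweep(
            state, problem, step_rng,
            n_leapfrog=n_leapfrog, step_size=steps[i],
            beta=schedule.betas[i] if has_map else 0.0,
            q=schedule.qs[i], e_min=schedule.e_min,
        )
        sweep_count[i] += 1
        if sweep_count[i] <= adapt_until:
            steps[i] *= 1.1 if res.accepted else 0.6
        nuisances[i] = new_state.nuisance
        return new_state.dof

    samples, stats = replica_exchange(
        [energy_fn(i) for i in range(n)],
        initial,
        step_fn,
        rng,
        n_sweeps,
        swap_stride=schedule.swap_stride,
    )
    return samples, stats, nuisances


def fit_rigid_symmetric(
    subunit: Structure,
    dmap: DensityMap | None,
    symmetry: SymmetrySpec,
    sigma: float = 2.0,
    box: BoxPrior | None = None,
    n_replicas: int = 4,
    n_sweeps: int = 100,
    n_burnin: int = 0,
    beta_min: float = 0.05,
    q_max: float = 1.1,
    n_leapfrog: int = 10,
    step_size: float = 0.05,
    force_field: str | None = "quartic",
    radii: float = 1.8,
    force_constant: float = 1.0,
    linkage_cutoff: float = 1.0,
    seed: int = 0,
    init_dof: np.ndarray | None = None,
    jitter: float = 0.0,
) -> FitResult:
    """Rigid fitting of a symmetric assembly from one subunit.

    Samples the six rigid degrees of freedom of the fundamental subunit
    with replica exchange; the remaining mates are virtual copies under
    ``symmetry`` and forces on them are backprojected.  With ``dmap=None``
    the target is the prior alone (box + force field): the packing
    problem.  Samples after burn-in are clustered by raw assembly RMSD.
    """
    rng = np.random.default_rng(seed)
    if dmap is None and box is None:
        raise ValueError("need a map or a box to confine the assembly")
    if box is None and dmap is not None:
        box = BoxPrior.from_map(dmap)
    model = RigidBodyModel([subunit.coords], [symmetry])
    problem = FitProblem(
        obs=dmap,
        model=model,
        sigma=sigma,
        force_field=force_field,
        radii=radii,
        force_constant=force_constant,
        box=box,
    )
    schedule = build_schedule(n_replicas, beta_min=beta_min, q_max=q_max)
    init = np.zeros(6) if init_dof is None else np.asarray(init_dof, dtype=float)
    samples, stats, _ = _replica_fit(
        problem, schedule, init, sigma, n_sweeps, rng,
        n_leapfrog=n_leapfrog, step_size=step_size, jitter=jitter,
    )
    kept = samples[n_burnin:]
    coord_sets = [model.coords(s) for s in kept]
    energies = np.array([problem.prior_energy(s) for s in kept])
    clusters = cluster_poses(coord_sets, linkage_cutoff, energies)
    rows = []
    for it, s in enumerate(kept):
        row = {"iteration": it, "e_prior": energies[it]}
        if dmap is not None:
            row["cross_correlation"] = cross_correlation(
                dmap, problem.model_values(s, sigma)
            )
        rows.append(row)
    return FitResult(
        trajectory=coord_sets,
        trace=pd.DataFrame(rows),
        final_coords=coord_sets[-1],
        clusters=clusters,
        stats=stats,
    )


def fit_multibody(
    subunits: list[Structure],
    dmap: DensityMap,
    symmetries: list[SymmetrySpec | None],
    sigma: float = 2.0,
    n_replicas: int = 4,
    n_sweeps: int = 100,
    n_burnin: int = 0,
    beta_min: float = 0.05,
    q_max: float = 1.1,
    n_leapfrog: int = 10,
    step_size: float = 0.05,
    force_field: str | None = "quartic",
    radii: float = 1.8,
    force_constant: float = 1.0,
    staged: bool = False,
    stage1_fraction: float = 0.5,
    linkage_cutoff: float = 1.0,
    seed: int = 0,
    init_dofs: np.ndarray | None = None,
    jitter: float = 0.0,
) -> FitResult:
    """Joint rigid fitting of several bodies (optionally symmetric).

    Six degrees of freedom per body are sampled jointly with replica
    exchange.  With ``staged`` the first ``stage1_fraction`` of the sweep
    budget runs with the non-bonded interactions switched off (fast
    convergence into the density), and the remainder refines with the
    force field on, starting from the lowest-energy stage-1 sample.
    """
    rng = np.random.default_rng(seed)
    model = RigidBodyModel([s.coords for s in subunits], symmetries)
    box = BoxPrior.from_map(dmap)
    schedule = build_schedule(n_replicas, beta_min=beta_min, q_max=q_max)
    init = (
        np.zeros(model.n_dof)
        if init_dofs is None
        else np.asarray(init_dofs, dtype=float).reshape(model.n_dof)
    )

    def make_problem(ff):
        return FitProblem(
            obs=dmap, model=model, sigma=sigma, force_field=ff,
            radii=radii, force_constant=force_constant, box=box,
        )

    stats: dict = {}
    if staged:
        n1 = max(int(n_sweeps * stage1_fraction), 1)
        problem1 = make_problem(None)
        samples1, stats1, _ = _replica_fit(
            problem1, schedule, init, sigma, n1, rng,
            n_leapfrog=n_leapfrog, step_size=step_size, jitter=jitter,
        )
        scores = [
            problem1.tempered_energy(s, 1.0, 1.0, sigma) for s in samples1
        ]
        init = samples1[int(np.argmin(scores))]
        n_sweeps = n_sweeps - n1
        stats["stage1"] = stats1
        jitter = 0.0

    problem = make_problem(force_field)
    samples, stats2, _ = _replica_fit(
        problem, schedule, init, sigma, n_sweeps, rng,
        n_leapfrog=n_leapfrog, step_size=step_size, jitter=jitter,
    )
    stats.update(stats2)
    kept = samples[n_burnin:]
    coord_sets = [model.coords(s) for s in kept]
    energies = np.array([problem.prior_energy(s) for s in kept])
    clusters = cluster_poses(coord_sets, linkage_cutoff, energies)
    rows = [
        {
            "iteration": it,
            "e_prior": energies[it],
            "cross_correlation": cross_correlation(
                dmap, problem.model_values(s, sigma)
            ),
        }
        for it, s in enumerate(kept)
    ]
    return FitResult(
        trajectory=coord_sets,
        trace=pd.DataFrame(rows),
        final_coords=coord_sets[-1],
        clusters=clusters,
        stats=stats,
    )
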