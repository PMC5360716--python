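"""Conformational priors: non-bonded force fields, soft-box confinement,
Tsallis reweighting and likelihood tempering.

The prior over conformations is a Boltzmann distribution exp(-E(theta)) of a
purely repulsive or weakly attractive non-bonded energy, multiplied by a
soft box that confines every atom to the bounding box of the thresholded
density map.  For tempering, the likelihood is raised to an inverse
temperature beta in [0, 1] and the non-bonded prior energy is flattened by
the Tsallis transformation

    u_q(E) = E_min + q/(q-1) * log[1 + (q-1)(E - E_min)],   q >= 1,

which reduces to E at q = 1 and grows only logarithmically in E for q > 1 —
high-energy (clashed) regions become traversable at large q without the
energy scale blowing up the way plain temperature scaling would.  The box
prior is not tempered: confinement to the map box must hold at every rung.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import expit

__all__ = [
    "BoxPrior",
    "quartic_repulsion",
    "ramped_lj",
    "box_log_prior",
    "tsallis_log_weight",
    "tsallis_energy",
    "tsallis_energy_weight",
]


@dataclasses.dataclass
class BoxPrior:
    """Soft logistic-wall confinement to an axis-aligned box.

    Each atom coordinate contributes log s(gamma (x - l)) + log s(gamma (u - x))
    per axis, with s the logistic sigmoid; gamma (1/Å) sets the wall
    steepness (default 1).  The box conventionally coincides with the
    bounding box of the thresholded map (lower corner at the grid origin).
    """

    lower: np.ndarray
    upper: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=np.float64).reshape(3)
        self.upper = np.asarray(self.upper, dtype=np.float64).reshape(3)
        if not np.all(self.upper > self.lower):
            raise ValueError("upper corner must exceed lower corner componentwise")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def from_map(cls, dmap, gamma: float = 1.0) -> "BoxPrior":
        lower, upper = dmap.box_corners()
        return cls(lower, upper, gamma)


def quartic_repulsion(
    coords: np.ndarray,
    radii: np.ndarray | float,
    k: float = 1.0,
    exclude: set[tuple[int, int]] | None = None,
) -> tuple[float, np.ndarray]:
    """Purely repulsive quartic contact energy and its exact gradient.

    For every atom pair closer than the sum of their contact radii
    ``d_ij``, the energy is ``k * (r_ij - d_ij)^4``; there is no attractive
    part.  Pairs are found with a KD-tree so only overlapping pairs are
    evaluated.  ``exclude`` holds ordered index pairs (i < j), typically
    covalent 1-2 neighbors, that are skipped.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    radii = np.broadcast_to(np.asarray(radii, dtype=np.float64), (n,))
    grad = np.zeros_like(coords)
    if n < 2:
        return 0.0, grad
    rmax = 2.0 * radii.max()
    pairs = cKDTree(coords).query_pairs(rmax, output_type="ndarray")
    energy = 0.0
    for i, j in pairs:
        if exclude and (int(i), int(j)) in exclude:
            continue
        d = radii[i] + radii[j]
        diff = coords[i] - coords[j]
        r = np.linalg.norm(diff)
        if r >= d or r == 0.0:
            continue
        gap = r - d  # negative
        energy += k * gap**4
        # dE/dr = 4 k gap^3; direction diff/r
        g = 4.0 * k * gap**3 * diff / r
        grad[i] += g
        grad[j] -= g
    return float(energy), grad


def ramped_lj(
    coords: np.ndarray,
    radii: np.ndarray | float,
    epsilon: float = 1.0,
    switch_fraction: float = 0.9,
    exclude: set[tuple[int, int]] | None = None,
) -> tuple[float, np.ndarray]:
    """Linearly ramped 12-6 Lennard-Jones energy and exact gradient.

    Outside the switch radius ``r_s = switch_fraction * r0`` (with
    ``r0 = radii_i + radii_j`` the pair minimum-energy distance) the energy
    is the standard LJ well ``epsilon [ (r0/r)^12 - 2 (r0/r)^6 ]``.  Inside
    ``r_s`` the steep core is replaced by its tangent line at ``r_s``, so
    energy and derivative are continuous and remain bounded for deeply
    clashed atoms — a requirement for stable leapfrog integration.

    All pairs are evaluated (no distance cutoff); intended for the modest
    system sizes of rigid-body assembly fitting.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    radii = np.broadcast_to(np.asarray(radii, dtype=np.float64), (n,))
    grad = np.zeros_like(coords)
    energy = 0.0
    if n < 2:
        return 0.0, grad

    def lj(r: float, r0: float) -> tuple[float, float]:
        s = (r0 / r) ** 6
        return epsilon * (s * s - 2.0 * s), epsilon * 12.0 * (s - s * s) / r

    for i in range(n - 1):
        diff = coords[i] - coords[i + 1 :]
        r = np.linalg.norm(diff, axis=1)
        for jj, rij in enumerate(r):
            j = i + 1 + jj
            if exclude and (i, j) in exclude:
                continue
            r0 = radii[i] + radii[j]
            rs = switch_fraction * r0
            if rij >= rs:
                e, de = lj(rij, r0)
            else:
                e_s, de_s = lj(rs, r0)
                e = e_s + de_s * (rij - rs)
                de = de_s
            energy += e
            if rij > 0:
                g = de * diff[jj] / rij
                grad[i] += g
                grad[j] -= g
    return float(energy), grad


def box_log_prior(
    coords: np.ndarray, box: BoxPrior
) -> tuple[float, np.ndarray]:
    """Log probability contribution of the soft box and its gradient.

    Stable for atoms far outside the box: log-sigmoids are evaluated as
    ``-log(1 + exp(-gamma x))`` via ``logaddexp``, which decays linearly
    rather than overflowing.  An atom exactly on a wall contributes
    ``log 1/2`` for that wall; an atom many ``1/gamma`` inside the box
    contributes essentially zero.
    """
    coords = np.asarray(coords, dtype=np.float64)
    g = box.gamma
    a = g * (coords - box.lower)  # distance past lower wall, scaled
    b = g * (box.upper - coords)
    logp = -np.logaddexp(0.0, -a).sum() - np.logaddexp(0.0, -b).sum()
    # d/dx log s(g(x-l)) = g * s(-g(x-l));  d/dx log s(g(u-x)) = -g * s(-g(u-x))
    grad = g * expit(-a) - g * expit(-b)
    return float(logp), grad


def tsallis_log_weight(E: float, q: float, E_min: float) -> float:
    """Log of the Tsallis weight [1 + (q-1)(E - E_min)]^(-q/(q-1)).

    Requires E >= E_min and q >= 1.  At q = 1 the analytic (Boltzmann)
    limit -(E - E_min) is returned.
    """
    E, q, E_min = float(E), float(q), float(E_min)
    if q < 1:
        raise ValueError("Tsallis q must be >= 1")
    dE = E - E_min
    if dE < 0:
        raise ValueError("E must not be below E_min")
    if q - 1.0 < 1e-14:
        return -dE
    return -(q / (q - 1.0)) * np.log1p((q - 1.0) * dE)


def tsallis_energy(E: float, q: float, E_min: float) -> float:
    """Tsallis-transformed energy u_q(E) = E_min - log weight.

    Adding E_min back makes u_1(E) = E exactly, so the tempered posterior
    energy at (beta=1, q=1) coincides with the untempered hybrid energy.
    """
    return float(E_min) - tsallis_log_weight(E, q, E_min)


def tsallis_energy_weight(E: float, q: float, E_min: float) -> float:
    """Derivative du_q/dE = q / [1 + (q-1)(E - E_min)].

    This is the factor by which Cartesian force-field gradients are scaled
    under Tsallis tempering (1 at q = 1; < 1 for clashed configurations at
    q > 1, which is what flattens the landscape).
    """
    E, q, E_min = float(E), float(q), float(E_min)
    if q < 1:
        raise ValueError("Tsallis q must be >= 1")
    dE = E - E_min
    if dE < 0:
        raise ValueError("E must not be below E_min")
    if q - 1.0 < 1e-14:
        return 1.0
    return q / (1.0 + (q - 1.0) * dE)
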