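"""Synthetic structures, assemblies and simulated maps with known truth.

Everything needed to exercise the fitting machinery is generated here:
self-avoiding toy polymers with a valid torsion topology and two hinged
domains, symmetric assemblies built from a subunit and a symmetry group,
and simulated density maps rendered by the forward model with optional
i.i.d. Gaussian voxel noise — exactly the noise model the likelihood
assumes, so nuisance-parameter recovery tests are well posed.  All
generators are deterministic given a seed, and each records its ground
truth (poses, torsions, noise precision) so tests can score recovery.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from cryofit.structures import Structure
from cryofit.maps import DensityMap
from cryofit.forward import render_density, default_bandwidth
from cryofit.dof import (
    TorsionTopology,
    SymmetrySpec,
    expand_symmetry,
    torsions_to_coords,
)

__all__ = [
    "make_toy_protein",
    "toy_domains",
    "make_hinge_pair",
    "simulate_map",
    "make_symmetric_assembly",
]

BOND_LENGTH = 3.8  # Å, consecutive-bead distance (Calpha-like trace)
CONTACT_DISTANCE = 4.0  # Å, minimum non-bonded bead separation


def make_toy_protein(n_residues: int, seed: int = 0) -> Structure:
    """A self-avoiding bead polymer with a chain-bond torsion topology.

    Beads are spaced ``BOND_LENGTH`` apart with direction changes limited
    to 20-100 degrees so 1-3 neighbors stay beyond contact distance; new
    beads are rejection-sampled until they clash with no earlier bead.
    The first and second halves of the chain serve as two rigid 'domains'
    joined by a hinge (see :func:`make_hinge_pair`).  Deterministic per
    seed.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    rng = np.random.default_rng(seed)
    while True:
        coords = _grow_chain(n_residues, rng)
        if coords is not None:
            break
    bonds = [(i, i + 1) for i in range(n_residues - 1)]
    return Structure(
        coords,
        names=["CA"] * n_residues,
        elements=["C"] * n_residues,
        chains=["A"] * n_residues,
        residue_ids=list(range(1, n_residues + 1)),
        bonds=bonds,
    )


def _grow_chain(n: int, rng: np.random.Generator) -> np.ndarray | None:
    coords = np.zeros((n, 3))
    direction = _random_unit(rng)
    coords[1] = coords[0] + BOND_LENGTH * direction
    for i in range(2, n):
        for _ in range(200):
            # bend the previous direction by 20-100 degrees about a random
            # perpendicular axis: keeps 1-3 distances above contact range
            bend = np.deg2rad(rng.uniform(20.0, 100.0))
            perp = np.cross(direction, _random_unit(rng))
            nrm = np.linalg.norm(perp)
            if nrm < 1e-8:
                continue
            perp /= nrm
            new_dir = np.cos(bend) * direction + np.sin(bend) * np.cross(
                perp, direction
            )
            new_dir /= np.linalg.norm(new_dir)
            candidate = coords[i - 1] + BOND_LENGTH * new_dir
            if i >= 2:
                d = cdist(candidate[None, :], coords[: i - 1]).ravel()
                if d.min() < CONTACT_DISTANCE:
                    continue
            coords[i] = candidate
            direction = new_dir
            break
        else:
            return None  # dead end; caller restarts with fresh randomness
    return coords


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def toy_domains(n_atoms: int) -> dict[str, np.ndarray]:
    """Index sets of the two rigid domains of a toy protein."""
    mid = n_atoms // 2
    return {
        "domain1": np.arange(0, mid),
        "domain2": np.arange(mid, n_atoms),
    }


def make_hinge_pair(
    protein: Structure, hinge_angle: float
) -> tuple[Structure, Structure]:
    """Open/closed conformer pair differing by one hinge torsion.

    The hinge is the rotatable bond joining the two domains; the closed
    state rotates domain 2 rigidly about it by ``hinge_angle`` (radians).
    Both domains keep their internal structure exactly.
    """
    topo = TorsionTopology.from_structure(protein)
    mid = protein.n_atoms // 2
    hinge_idx = None
    for i, t in enumerate(topo.torsions):
        if t["axis"] == (mid - 1, mid):
            hinge_idx = i
            break
    if hinge_idx is None:
        raise ValueError("no rotatable hinge bond between the domains")
    angles = topo.measure(protein.coords)
    angles[hinge_idx] += hinge_angle
    closed = protein.with_coords(
        torsions_to_coords(angles, topo, protein.coords)
    )
    return protein, closed


def simulate_map(
    structure: Structure | np.ndarray,
    resolution: float,
    spacing: float,
    noise_lambda: float | None = None,
    seed: int = 0,
    padding_sigmas: float = 5.0,
) -> DensityMap:
    """Render a simulated density map of a structure.

    The Gaussian-kernel forward model is evaluated at
    ``sigma = 0.225 * resolution`` on a grid padded ``padding_sigmas *
    sigma`` beyond the structure's bounding box.  If ``noise_lambda`` is
    given, i.i.d. Gaussian noise of variance ``1 / noise_lambda`` is added
    per voxel — the generative model matching the Gaussian likelihood.
    """
    coords = structure.coords if isinstance(structure, Structure) else np.asarray(structure)
    sigma = default_bandwidth(resolution)
    pad = padding_sigmas * sigma
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    grid = DensityMap(np.zeros(shape), lo, spacing)
    values = render_density(coords, grid, sigma)
    if noise_lambda is not None:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_lambda**-0.5, size=values.shape)
    return DensityMap(values, lo, spacing)


def make_symmetric_assembly(
    subunit: Structure, spec: SymmetrySpec
) -> tuple[Structure, dict]:
    """Expand a subunit into a symmetric assembly (one chain per mate).

    Returns the merged structure and a ground-truth record holding the
    symmetry spec and the fundamental subunit coordinates; re-expanding
    the recorded subunit with the recorded spec reproduces the assembly
    exactly.
    """
    mates = expand_symmetry(subunit.coords, spec)
    chain_ids = [chr(ord("A") + m % 26) for m in range(len(mates))]
    coords = np.concatenate(mates, axis=0)
    k = subunit.n_atoms
    names, elements, chains, resids = [], [], [], []
    for m, cid in enumerate(chain_ids):
        names.extend(subunit.names)
        elements.extend(subunit.elements)
        chains.extend([cid] * k)
        resids.extend(subunit.residue_ids)
    assembly = Structure(coords, names, elements, chains, resids)
    truth = {
        "symmetry": spec,
        "subunit_coords": subunit.coords.copy(),
        "n_mates": len(mates),
    }
    return assembly, truth
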