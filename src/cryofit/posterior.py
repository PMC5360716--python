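"""Assembling the tempered posterior energy over conformational DoF.

A :class:`FitProblem` bundles the observed (preprocessed) map, a
conformational parameterization, the blur bandwidth, and the priors
(non-bonded force field, soft box).  Its central service is the tempered
posterior energy and its gradient over the flat DoF vector:

    U(theta) = beta * lambda * E_map(theta, alpha)
             + u_q(E(theta))            (Tsallis-transformed force field)
             - log box(theta)

which at (beta=1, q=1) is exactly the hybrid energy E + lambda E_map plus
the box terms.  Gradients flow: voxel residuals -> Cartesian forces through
the Gaussian kernel -> projection onto rigid/torsion coordinates (with
symmetry-mate forces backprojected onto the fundamental subunit).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cryofit.maps import DensityMap
from cryofit.forward import render_density, render_gradient
from cryofit.priors import (
    BoxPrior,
    quartic_repulsion,
    ramped_lj,
    box_log_prior,
    tsallis_energy,
    tsallis_energy_weight,
)
from cryofit.dof import (
    RigidDoF,
    SymmetrySpec,
    TorsionTopology,
    rigid_apply,
    rigid_gradient,
    torsions_to_coords,
    project_torsion_gradient,
    symmetry_transforms,
    backproject_symmetry_gradient,
)

__all__ = ["RigidBodyModel", "TorsionModel", "CartesianModel", "FitProblem"]


class RigidBodyModel:
    """One or more rigid bodies, each optionally expanded by a symmetry.

    The flat DoF vector concatenates six coordinates per body
    (translation, axis-angle rotation).  Model atoms are ordered body by
    body, and within a body mate by mate (mate 0 first).
    """

    def __init__(
        self,
        references: list[np.ndarray],
        symmetries: list[SymmetrySpec | None] | None = None,
    ):
        self.references = [np.asarray(r, dtype=np.float64) for r in references]
        self.symmetries = symmetries or [None] * len(self.references)
        if len(self.symmetries) != len(self.references):
            raise ValueError("one symmetry spec (or None) per body required")
        self._transforms = [
            None if s is None else symmetry_transforms(s) for s in self.symmetries
        ]

    @property
    def n_bodies(self) -> int:
        return len(self.references)

    @property
    def n_dof(self) -> int:
        return 6 * self.n_bodies

    @property
    def n_atoms(self) -> int:
        return sum(
            r.shape[0] * (1 if t is None else len(t))
            for r, t in zip(self.references, self._transforms)
        )

    def _bodies(self, flat: np.ndarray) -> list[RigidDoF]:
        flat = np.asarray(flat, dtype=np.float64).reshape(self.n_dof)
        return [
            RigidDoF(flat[6 * b : 6 * b + 3], flat[6 * b + 3 : 6 * b + 6])
            for b in range(self.n_bodies)
        ]

    def coords(self, flat: np.ndarray) -> np.ndarray:
        out = []
        for dof, ref, transforms in zip(
            self._bodies(flat), self.references, self._transforms
        ):
            x = rigid_apply(dof, ref)
            if transforms is None:
                out.append(x)
            else:
                for R, t in transforms:
                    out.append(x @ R.T + t)
        return np.concatenate(out, axis=0)

    def fundamental_coords(self, flat: np.ndarray) -> list[np.ndarray]:
        """Posed coordinates of each body's fundamental copy (mate 0)."""
        return [
            rigid_apply(dof, ref)
            for dof, ref in zip(self._bodies(flat), self.references)
        ]

    def gradient(self, flat: np.ndarray, cart_grad: np.ndarray) -> np.ndarray:
        grads = []
        offset = 0
        for dof, ref, spec, transforms in zip(
            self._bodies(flat), self.references, self.symmetries, self._transforms
        ):
            k = ref.shape[0]
            if transforms is None:
                g = cart_grad[offset : offset + k]
                grads.append(rigid_gradient(dof, ref, g))
                offset += k
            else:
                mate_grads = [
                    cart_grad[offset + m * k : offset + (m + 1) * k]
                    for m in range(len(transforms))
                ]
                grads.append(
                    backproject_symmetry_gradient(mate_grads, spec, dof, ref)
                )
                offset += k * len(transforms)
        return np.concatenate(grads)


class TorsionModel:
    """A single chain parameterized by torsion angles, optionally with a
    leading rigid-body block (flat layout: [rigid(6)?, angles])."""

    def __init__(
        self,
        reference: np.ndarray,
        topology: TorsionTopology,
        include_rigid: bool = False,
    ):
        self.reference = np.asarray(reference, dtype=np.float64)
        self.topology = topology
        self.include_rigid = include_rigid

    @property
    def n_dof(self) -> int:
        return (6 if self.include_rigid else 0) + self.topology.n_torsions

    @property
    def n_atoms(self) -> int:
        return self.reference.shape[0]

    def _split(self, flat: np.ndarray) -> tuple[RigidDoF | None, np.ndarray]:
        flat = np.asarray(flat, dtype=np.float64).reshape(self.n_dof)
        if self.include_rigid:
            return RigidDoF(flat[:3], flat[3:6]), flat[6:]
        return None, flat

    def coords(self, flat: np.ndarray) -> np.ndarray:
        rigid, angles = self._split(flat)
        y = torsions_to_coords(angles, self.topology, self.reference)
        return y if rigid is None else rigid_apply(rigid, y)

    def gradient(self, flat: np.ndarray, cart_grad: np.ndarray) -> np.ndarray:
        rigid, angles = self._split(flat)
        y = torsions_to_coords(angles, self.topology, self.reference)
        if rigid is None:
            return project_torsion_gradient(y, cart_grad, self.topology)
        from cryofit.dof import rotation_matrix

        R = rotation_matrix(rigid.rotation)
        g_body = cart_grad @ R  # rotate forces into the body frame
        tors = project_torsion_gradient(y, g_body, self.topology)
        rig = rigid_gradient(rigid, y, cart_grad)
        return np.concatenate([rig, tors])


class CartesianModel:
    """Raw Cartesian coordinates as degrees of freedom."""

    def __init__(self, n_atoms: int):
        self._n_atoms = n_atoms

    @property
    def n_dof(self) -> int:
        return 3 * self._n_atoms

    @property
    def n_atoms(self) -> int:
        return self._n_atoms

    def coords(self, flat: np.ndarray) -> np.ndarray:
        return np.asarray(flat, dtype=np.float64).reshape(self._n_atoms, 3)

    def gradient(self, flat: np.ndarray, cart_grad: np.ndarray) -> np.ndarray:
        return np.asarray(cart_grad, dtype=np.float64).ravel()


@dataclasses.dataclass
class FitProblem:
    """Observed map + parameterization + priors = a sampling target.

    Parameters
    ----------
    obs : DensityMap or None
        Preprocessed experimental map.  None runs prior-only (packing)
        problems.
    model : RigidBodyModel | TorsionModel | CartesianModel
        Maps the flat DoF vector to model-atom coordinates and projects
        Cartesian gradients back.
    sigma : float
        Default blur bandwidth (Å) for rendering.
    force_field : {'quartic', 'lj', None}
        Non-bonded prior energy over all model atoms (including symmetry
        mates).
    radii : float or ndarray
        Contact radii (Å) per model atom for the force field.
    force_constant : float
        Energy scale k of the quartic repulsion (or epsilon of the LJ well).
    exclude_pairs : set of (i, j)
        Model-atom index pairs (i < j) excluded from the force field,
        typically covalent neighbors.
    box : BoxPrior or None
        Soft confinement to the map bounding box.
    """

    obs: DensityMap | None
    model: object
    sigma: float
    force_field: str | None = None
    radii: float | np.ndarray = 2.0
    force_constant: float = 1.0
    exclude_pairs: set | None = None
    box: BoxPrior | None = None
    kernel_cutoff: float = 5.0

    def model_values(self, flat: np.ndarray, sigma: float | None = None) -> np.ndarray:
        if self.obs is None:
            raise ValueError("no observed map in this problem")
        return render_density(
            self.model.coords(flat),
            self.obs,
            self.sigma if sigma is None else sigma,
            cutoff=self.kernel_cutoff,
        )

    def _force_field(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        if self.force_field == "quartic":
            return quartic_repulsion(
                coords, self.radii, self.force_constant, self.exclude_pairs
            )
        if self.force_field == "lj":
            return ramped_lj(
                coords, self.radii, self.force_constant, exclude=self.exclude_pairs
            )
        if self.force_field is None:
            return 0.0, np.zeros_like(coords)
        raise ValueError(f"unknown force field {self.force_field!r}")

    def prior_energy(self, flat: np.ndarray) -> float:
        """Non-bonded prior energy E(theta) (without box terms)."""
        return self._force_field(self.model.coords(flat))[0]

    def tempered_energy(
        self,
        flat: np.ndarray,
        alpha: float,
        lam: float,
        sigma: float | None = None,
        beta: float = 1.0,
        q: float = 1.0,
        e_min: float = 0.0,
    ) -> float:
        """Tempered posterior energy only (no gradient; used for swaps)."""
        sigma = self.sigma if sigma is None else sigma
        coords = self.model.coords(flat)
        energy = 0.0
        if beta > 0.0 and self.obs is not None:
            f = render_density(coords, self.obs, sigma, cutoff=self.kernel_cutoff)
            resid = np.where(self.obs.mask, self.obs.values - alpha * f, 0.0)
            energy += beta * lam * 0.5 * float((resid**2).sum())
        if self.force_field is not None:
            energy += tsallis_energy(self._force_field(coords)[0], q, e_min)
        if self.box is not None:
            energy -= box_log_prior(coords, self.box)[0]
        return energy

    def tempered_energy_gradient(
        self,
        flat: np.ndarray,
        alpha: float,
        lam: float,
        sigma: float | None = None,
        beta: float = 1.0,
        q: float = 1.0,
        e_min: float = 0.0,
    ) -> tuple[float, np.ndarray]:
        """Tempered posterior energy and its gradient over the flat DoF.

        beta scales the likelihood (the map restraint); q flattens the
        non-bonded prior via the Tsallis transformation with reference
        energy ``e_min``; the box prior is applied untempered.  Constant
        (theta-independent) normalization terms are dropped.
        """
        if not (0.0 <= beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        sigma = self.sigma if sigma is None else sigma
        coords = self.model.coords(flat)
        energy = 0.0
        cart = np.zeros_like(coords)

        if beta > 0.0 and self.obs is not None:
            f = render_density(coords, self.obs, sigma, cutoff=self.kernel_cutoff)
            resid = np.where(self.obs.mask, self.obs.values - alpha * f, 0.0)
            e_map = 0.5 * float((resid**2).sum())
            energy += beta * lam * e_map
            weights = beta * lam * (-alpha) * resid
            cart += render_gradient(
                coords, self.obs, sigma, weights, cutoff=self.kernel_cutoff
            )

        if self.force_field is not None:
            e_ff, g_ff = self._force_field(coords)
            energy += tsallis_energy(e_ff, q, e_min)
            cart += tsallis_energy_weight(e_ff, q, e_min) * g_ff

        if self.box is not None:
            logp, g_box = box_log_prior(coords, self.box)
            energy -= logp
            cart -= g_box

        return energy, self.model.gradient(flat, cart)
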