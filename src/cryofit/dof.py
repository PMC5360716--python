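"""Conformational degrees of freedom and symmetry.

Three parameterizations are supported and freely combined:

* **Cartesian** — raw atom coordinates.
* **Rigid body** — three translational plus three rotational degrees of
  freedom per body; rotations live in the Lie algebra so(3) as axis-angle
  vectors mapped to rotation matrices by the exponential map.  Gradients of
  Cartesian energies are pulled back through the exact differential of the
  exponential map (the right Jacobian), not a small-angle approximation.
* **Torsion angles** — dihedral angles on a rooted tree of covalent bonds.
  Changing an angle rotates exactly its downstream subtree about the bond
  axis, preserving all bond lengths and bond angles; Cartesian gradients
  are projected onto the angles by a single leaf-to-root traversal that
  accumulates subtree force and torque sums, so the full Jacobian is never
  materialized.

Symmetric assemblies are modelled through *virtual* symmetry mates: only
the fundamental subunit carries degrees of freedom, the mates are generated
by a cyclic (C_n), dihedral (D_n, 2n elements) or helical (screw) group,
and forces acting on the mates are backprojected onto the subunit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidDoF",
    "DoFVector",
    "TorsionTopology",
    "SymmetrySpec",
    "skew",
    "rotation_matrix",
    "right_jacobian",
    "canonicalize_rotvec",
    "rigid_apply",
    "rigid_gradient",
    "measure_dihedral",
    "torsions_to_coords",
    "project_torsion_gradient",
    "symmetry_transforms",
    "expand_symmetry",
    "backproject_symmetry_gradient",
]


# ---------------------------------------------------------------------------
# rotations


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix [v]_x with [v]_x w = v x w."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Exponential map so(3) -> SO(3) for an axis-angle vector."""
    return Rotation.from_rotvec(np.asarray(rotvec, dtype=np.float64)).as_matrix()


def right_jacobian(rotvec: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of the exponential map at ``rotvec``.

    Relates a perturbation of the axis-angle coordinates to the body-frame
    angular increment: exp(phi + d phi) ~ exp(phi) exp(J_r(phi) d phi).
    A fourth-order series is used below |phi| = 1e-4.
    """
    phi = np.asarray(rotvec, dtype=np.float64)
    theta = np.linalg.norm(phi)
    K = skew(phi)
    if theta < 1e-4:
        return np.eye(3) - 0.5 * K + (1.0 / 6.0) * (K @ K)
    t2 = theta * theta
    return (
        np.eye(3)
        - (1.0 - np.cos(theta)) / t2 * K
        + (theta - np.sin(theta)) / (t2 * theta) * (K @ K)
    )


def canonicalize_rotvec(rotvec: np.ndarray) -> np.ndarray:
    """Wrap an axis-angle vector so its magnitude lies in [0, pi].

    Keeps the parameterization away from the exponential-map singularity
    at |phi| = 2 pi without changing the rotation it represents.
    """
    phi = np.asarray(rotvec, dtype=np.float64).copy()
    theta = np.linalg.norm(phi)
    if theta > np.pi:
        wrapped = theta % (2.0 * np.pi)
        if wrapped > np.pi:
            wrapped -= 2.0 * np.pi
        phi *= wrapped / theta
    return phi


@dataclasses.dataclass
class RigidDoF:
    """Six rigid-body degrees of freedom: translation (Å) and rotation.

    The rotation is an axis-angle (Lie algebra) vector in radians; the pose
    acts as ``x -> R(rotation) x + translation``.
    """

    translation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )
    rotation: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.rotation = canonicalize_rotvec(
            np.asarray(self.rotation, dtype=np.float64).reshape(3)
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "RigidDoF":
        v = np.asarray(v, dtype=np.float64).reshape(6)
        return cls(v[:3], v[3:])

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation])


def rigid_apply(dof: RigidDoF, coords: np.ndarray) -> np.ndarray:
    """Apply the rigid transform: R x + t per atom."""
    R = rotation_matrix(dof.rotation)
    return np.asarray(coords, dtype=np.float64) @ R.T + dof.translation


def rigid_gradient(
    dof: RigidDoF, coords: np.ndarray, cart_grad: np.ndarray
) -> np.ndarray:
    """Pull a Cartesian gradient back onto the six rigid coordinates.

    ``coords`` are the body-frame (untransformed) positions and
    ``cart_grad`` the gradient with respect to the transformed positions.
    The translation block is the total force; the rotation block is
    ``J_r(phi)^T sum_k v_k x (R^T g_k)``, the exact differential of the
    exponential-map composition (at phi = 0 this is the familiar torque).
    """
    coords = np.asarray(coords, dtype=np.float64)
    g = np.asarray(cart_grad, dtype=np.float64)
    R = rotation_matrix(dof.rotation)
    g_body = g @ R  # R^T g_k, row-wise
    torque = np.cross(coords, g_body).sum(axis=0)
    rot_grad = right_jacobian(dof.rotation).T @ torque
    return np.concatenate([g.sum(axis=0), rot_grad])


@dataclasses.dataclass
class DoFVector:
    """Concatenated degrees of freedom: per-body rigid blocks + torsions.

    The flat layout is ``[body0 (6), body1 (6), ..., torsion angles]``;
    :meth:`pack` / :meth:`unpack` are exact inverses.
    """

    rigid_bodies: list[RigidDoF]
    torsions: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(0)
    )

    def __post_init__(self) -> None:
        self.torsions = np.asarray(self.torsions, dtype=np.float64).reshape(-1)

    @property
    def size(self) -> int:
        return 6 * len(self.rigid_bodies) + self.torsions.size

    def pack(self) -> np.ndarray:
        parts = [b.as_vector() for b in self.rigid_bodies]
        parts.append(self.torsions)
        return np.concatenate(parts) if parts else np.zeros(0)

    @classmethod
    def unpack(
        cls, flat: np.ndarray, n_bodies: int, n_torsions: int
    ) -> "DoFVector":
        flat = np.asarray(flat, dtype=np.float64).reshape(-1)
        if flat.size != 6 * n_bodies + n_torsions:
            raise ValueError("flat vector length does not match layout")
        bodies = [
            RigidDoF(flat[6 * i : 6 * i + 3], flat[6 * i + 3 : 6 * i + 6])
            for i in range(n_bodies)
        ]
        return cls(bodies, flat[6 * n_bodies :])


# ---------------------------------------------------------------------------
# torsion angles


def measure_dihedral(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> float:
    """Signed dihedral angle (radians, in (-pi, pi]) of four points.

    Positive rotation follows the right-hand rule about the b -> c axis.
    """
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(a, dtype=np.float64) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


class TorsionTopology:
    """Rooted bond tree mapping dihedral angles to downstream atom sets.

    Built from a covalent-bond edge list (which must be a forest); each
    tree is rooted at its lowest-index atom.  A bond (u, v), with u the
    parent, defines a rotatable torsion if u itself has a parent and v has
    at least one child: the dihedral is measured on the quadruple
    (parent(u), u, v, first child of v) and rotating it moves the whole
    subtree below v.
    """

    def __init__(self, n_atoms: int, bonds: list[tuple[int, int]]):
        self.n_atoms = n_atoms
        adj: list[list[int]] = [[] for _ in range(n_atoms)]
        for i, j in bonds:
            adj[i].append(j)
            adj[j].append(i)
        self.parent = np.full(n_atoms, -1, dtype=int)
        self.depth = np.zeros(n_atoms, dtype=int)
        children: list[list[int]] = [[] for _ in range(n_atoms)]
        visited = np.zeros(n_atoms, dtype=bool)
        order = []
        for root in range(n_atoms):
            if visited[root]:
                continue
            stack = [root]
            visited[root] = True
            while stack:
                u = stack.pop()
                order.append(u)
                for w in sorted(adj[u], reverse=True):
                    if not visited[w]:
                        visited[w] = True
                        self.parent[w] = u
                        self.depth[w] = self.depth[u] + 1
                        children[w] = []
                        stack.append(w)
            # re-derive children in sorted order
        for w in range(n_atoms):
            if self.parent[w] >= 0:
                children[self.parent[w]].append(w)
        for u in range(n_atoms):
            children[u].sort()
        self.children = children
        self._traversal = order  # parents precede children

        # rotatable torsions, ordered parent-first (shallow to deep)
        self.torsions: list[dict] = []
        for v in order:
            u = self.parent[v]
            if u < 0 or self.parent[u] < 0 or not children[v]:
                continue
            downstream = self._subtree(v)
            downstream.remove(v)
            self.torsions.append(
                {
                    "axis": (u, v),
                    "quad": (self.parent[u], u, v, children[v][0]),
                    "downstream": np.array(sorted(downstream), dtype=int),
                }
            )
        self.torsions.sort(key=lambda t: self.depth[t["axis"][1]])

    @classmethod
    def from_structure(cls, structure) -> "TorsionTopology":
        bonds = structure.bonds
        if bonds is None:
            from cryofit.structures import _chain_bonds

            bonds = _chain_bonds(structure)
        return cls(structure.n_atoms, bonds)

    def _subtree(self, v: int) -> set[int]:
        out = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for w in self.children[u]:
                out.add(w)
                stack.append(w)
        return out

    @property
    def n_torsions(self) -> int:
        return len(self.torsions)

    def measure(self, coords: np.ndarray) -> np.ndarray:
        """Dihedral angle of every rotatable torsion in ``coords``."""
        coords = np.asarray(coords, dtype=np.float64)
        return np.array(
            [measure_dihedral(*(coords[i] for i in t["quad"])) for t in self.torsions]
        )


def torsions_to_coords(
    angles: np.ndarray, topology: TorsionTopology, reference: np.ndarray
) -> np.ndarray:
    """Rebuild Cartesian coordinates from torsion angles.

    Starting from the reference coordinates, each torsion's downstream
    subtree is rotated about the current bond axis by the difference
    between the requested and the reference angle, processed from the root
    outwards.  Bond lengths and bond angles are exactly those of the
    reference; the measured dihedrals of the result equal ``angles``.
    The rebuild is deterministic: identical inputs give bit-identical
    output.
    """
    angles = _wrap_angle(np.asarray(angles, dtype=np.float64))
    if angles.size != topology.n_torsions:
        raise ValueError("one angle per rotatable torsion required")
    coords = np.asarray(reference, dtype=np.float64).copy()
    ref_angles = topology.measure(coords)
    for t, angle, ref in zip(topology.torsions, angles, ref_angles):
        delta = float(_wrap_angle(angle - ref))
        if delta == 0.0:
            continue
        u, v = t["axis"]
        # axis points child -> parent so a positive delta increases the
        # measured dihedral (right-hand rule of the 4-point convention)
        axis = coords[u] - coords[v]
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(axis * delta).as_matrix()
        p = coords[v]
        idx = t["downstream"]
        coords[idx] = (coords[idx] - p) @ R.T + p
    return coords


def project_torsion_gradient(
    coords: np.ndarray, cart_grad: np.ndarray, topology: TorsionTopology
) -> np.ndarray:
    """Project a Cartesian gradient onto the torsion angles.

    The derivative of atom k under torsion i (axis a_i through point p_i)
    is ``a_i x (x_k - p_i)``, so the angle gradient is
    ``a_i . (T_i - p_i x F_i)`` with ``F_i`` and ``T_i`` the force and
    torque sums over the downstream subtree.  Subtree sums are accumulated
    in one leaf-to-root pass, avoiding the K x n_torsions Jacobian.
    """
    coords = np.asarray(coords, dtype=np.float64)
    g = np.asarray(cart_grad, dtype=np.float64)
    force = g.copy()  # will become subtree sums
    torque = np.cross(coords, g)
    for v in reversed(topology._traversal):
        u = topology.parent[v]
        if u >= 0:
            force[u] += force[v]
            torque[u] += torque[v]
    out = np.empty(topology.n_torsions)
    for i, t in enumerate(topology.torsions):
        u, v = t["axis"]
        axis = coords[u] - coords[v]  # child -> parent, as in the rebuild
        axis /= np.linalg.norm(axis)
        p = coords[v]
        # downstream of the torsion excludes v itself: subtract its own term
        F = force[v] - g[v]
        T = torque[v] - np.cross(coords[v], g[v])
        out[i] = axis @ (T - np.cross(p, F))
    return out


# ---------------------------------------------------------------------------
# symmetry


@dataclasses.dataclass
class SymmetrySpec:
    """Point-group or helical symmetry of an assembly.

    kind : 'cyclic' (C_n, n mates), 'dihedral' (D_n, 2n mates) or
    'helical' (n mates along a screw axis).  ``axis`` is the symmetry axis
    direction through ``point``; for dihedral symmetry ``perp_axis`` is the
    direction of the 2-fold axis (default: any unit vector perpendicular to
    ``axis``); for helical symmetry ``rise`` (Å) and ``twist`` (radians)
    define the screw generator.
    """

    kind: str
    n: int
    axis: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    point: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    rise: float = 0.0
    twist: float = 0.0
    perp_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cyclic", "dihedral", "helical"):
            raise ValueError(f"unknown symmetry kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("symmetry order n must be >= 1")
        self.axis = np.asarray(self.axis, dtype=np.float64).reshape(3)
        self.axis = self.axis / np.linalg.norm(self.axis)
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        if self.kind == "dihedral":
            if self.perp_axis is None:
                # any direction perpendicular to the main axis
                trial = np.array([1.0, 0.0, 0.0])
                if abs(trial @ self.axis) > 0.9:
                    trial = np.array([0.0, 1.0, 0.0])
                perp = trial - (trial @ self.axis) * self.axis
                self.perp_axis = perp / np.linalg.norm(perp)
            else:
                self.perp_axis = np.asarray(
                    self.perp_axis, dtype=np.float64
                ).reshape(3)
                self.perp_axis /= np.linalg.norm(self.perp_axis)

    @property
    def n_mates(self) -> int:
        return 2 * self.n if self.kind == "dihedral" else self.n


def symmetry_transforms(spec: SymmetrySpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Affine transforms (R, t) of all mates; mate m maps x to R x + t.

    Mate 0 is always the identity.
    """
    out: list[tuple[np.ndarray, np.ndarray]] = []
    p = spec.point
    if spec.kind == "helical":
        for m in range(spec.n):
            R = Rotation.from_rotvec(spec.axis * (m * spec.twist)).as_matrix()
            t = p - R @ p + m * spec.rise * spec.axis
            out.append((R, t))
        return out
    for m in range(spec.n):
        R = Rotation.from_rotvec(spec.axis * (2.0 * np.pi * m / spec.n)).as_matrix()
        out.append((R, p - R @ p))
    if spec.kind == "dihedral":
        F = Rotation.from_rotvec(spec.perp_axis * np.pi).as_matrix()
        for m in range(spec.n):
            R = out[m][0] @ F
            out.append((R, p - R @ p))
    return out


def expand_symmetry(coords: np.ndarray, spec: SymmetrySpec) -> list[np.ndarray]:
    """Coordinates of every symmetry mate (mate 0 equals the input)."""
    coords = np.asarray(coords, dtype=np.float64)
    return [coords @ R.T + t for R, t in symmetry_transforms(spec)]


def backproject_symmetry_gradient(
    mate_gradients: list[np.ndarray],
    spec: SymmetrySpec,
    dof: RigidDoF,
    reference: np.ndarray,
) -> np.ndarray:
    """Fold per-mate Cartesian gradients back onto the subunit's rigid DoF.

    The fundamental subunit is ``x = R(dof) v + t(dof)`` applied to the
    reference coordinates ``v``; mate m is ``S_m x + c_m``.  The gradient of
    the total energy with respect to the six rigid coordinates is obtained
    by rotating each mate's gradient back (``S_m^T g_m``), summing, and
    applying :func:`rigid_gradient`.
    """
    transforms = symmetry_transforms(spec)
    if len(mate_gradients) != len(transforms):
        raise ValueError(
            f"expected {len(transforms)} mate gradients, got {len(mate_gradients)}"
        )
    total = np.zeros_like(np.asarray(reference, dtype=np.float64))
    for (S, _), g in zip(transforms, mate_gradients):
        total += np.asarray(g, dtype=np.float64) @ S
    return rigid_gradient(dof, reference, total)
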