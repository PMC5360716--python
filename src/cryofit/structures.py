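"""Atomic structures: coordinates, minimal topology, PDB/mmCIF round trip.

The :class:`Structure` container keeps what density fitting needs — atom
positions, identity metadata and a covalent-bond forest per chain that the
torsion parameterization walks.  File I/O goes through gemmi, so anything
gemmi reads (PDB, mmCIF) can be fitted.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np

import gemmi

__all__ = ["Structure", "read_structure", "write_structure", "write_models"]


@dataclasses.dataclass
class Structure:
    """Atom coordinates with chain/bond topology.

    Parameters
    ----------
    coords : ndarray, shape (K, 3)
        Atom positions in Å.
    names, elements, chains : sequences of str, length K
        Atom name, element symbol and chain identifier per atom.
    residue_ids : sequence of int, length K
        Residue sequence number per atom.
    bonds : list of (int, int)
        Covalent bonds as index pairs.  When present the bond graph must be
        a forest (no cycles) — the requirement for a valid torsion tree.
    """

    coords: np.ndarray
    names: list[str] | None = None
    elements: list[str] | None = None
    chains: list[str] | None = None
    residue_ids: list[int] | None = None
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (K, 3)")
        k = self.n_atoms
        if k < 1:
            raise ValueError("structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.names is None:
            self.names = [f"C{i}" for i in range(k)]
        if self.elements is None:
            self.elements = ["C"] * k
        if self.chains is None:
            self.chains = ["A"] * k
        if self.residue_ids is None:
            self.residue_ids = list(range(1, k + 1))
        for field in ("names", "elements", "chains", "residue_ids"):
            if len(getattr(self, field)) != k:
                raise ValueError(f"{field} must have one entry per atom")
        if self.bonds is not None:
            self._check_forest()

    def _check_forest(self) -> None:
        # union-find cycle detection
        parent = list(range(self.n_atoms))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in self.bonds:
            ri, rj = find(i), find(j)
            if ri == rj:
                raise ValueError("bond topology contains a cycle")
            parent[ri] = rj

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure with replaced coordinates."""
        return Structure(
            np.asarray(coords, dtype=np.float64).copy(),
            list(self.names),
            list(self.elements),
            list(self.chains),
            list(self.residue_ids),
            None if self.bonds is None else list(self.bonds),
        )

    def select(self, indices: np.ndarray) -> "Structure":
        """Sub-structure restricted to ``indices`` (bonds are dropped)."""
        idx = np.asarray(indices)
        return Structure(
            self.coords[idx],
            [self.names[i] for i in idx],
            [self.elements[i] for i in idx],
            [self.chains[i] for i in idx],
            [self.residue_ids[i] for i in idx],
        )


def _chain_bonds(structure: Structure) -> list[tuple[int, int]]:
    """Sequential backbone bonds within each chain (fallback topology)."""
    bonds = []
    for i in range(structure.n_atoms - 1):
        if structure.chains[i] == structure.chains[i + 1]:
            bonds.append((i, i + 1))
    return bonds


def read_structure(path: str | os.PathLike, model: int = 0) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    mdl = st[model]
    coords, names, elements, chains, resids = [], [], [], [], []
    for chain in mdl:
        for residue in chain:
            for atom in residue:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                names.append(atom.name)
                elements.append(atom.element.name)
                chains.append(chain.name)
                resids.append(residue.seqid.num)
    return Structure(np.array(coords), names, elements, chains, resids)


def _to_gemmi(structure: Structure, coords: np.ndarray | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "cryofit"
    mdl = gemmi.Model("1")
    xyz = structure.coords if coords is None else coords
    chain_obj: gemmi.Chain | None = None
    res_obj: gemmi.Residue | None = None
    prev = (None, None)
    for i in range(structure.n_atoms):
        key = (structure.chains[i], structure.residue_ids[i])
        if chain_obj is None or key[0] != prev[0]:
            chain_obj = gemmi.Chain(structure.chains[i])
            mdl.add_chain(chain_obj)
            chain_obj = mdl[-1]
            res_obj = None
        if res_obj is None or key != prev:
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(structure.residue_ids[i], " ")
            chain_obj.add_residue(res)
            res_obj = chain_obj[-1]
        atom = gemmi.Atom()
        atom.name = structure.names[i]
        atom.element = gemmi.Element(structure.elements[i])
        atom.pos = gemmi.Position(*xyz[i])
        res_obj.add_atom(atom)
        prev = key
    st.add_model(mdl)
    return st


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a structure as PDB (or mmCIF if the path ends in .cif)."""
    st = _to_gemmi(structure)
    path = str(path)
    if path.endswith(".cif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


def write_models(
    structure: Structure, coord_sets: list[np.ndarray], path: str | os.PathLike
) -> None:
    """Write a multi-model PDB trajectory (one MODEL per coordinate set)."""
    st = gemmi.Structure()
    st.name = "cryofit-trajectory"
    for m, xyz in enumerate(coord_sets, start=1):
        single = _to_gemmi(structure, np.asarray(xyz))
        mdl = single[0].clone()
        mdl.num = m
        st.add_model(mdl)
    st.write_pdb(str(path))
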