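"""Molecular data model and rigid-body geometry.

The package works entirely in Cartesian coordinates in the receptor frame:
a ligand pose is a list of atom coordinates transformed directly by
rotation/translation matrices, with no internal-coordinate representation.
All distances are in Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "Atom",
    "Molecule",
    "Receptor",
    "RigidTransform",
    "Pose",
    "neighbor_atom",
    "apply_transform",
    "random_uniform_rotation",
    "random_small_perturbation",
    "ligand_rmsd",
    "detect_rotatable_bonds",
]

# Bondi-style van der Waals radii (A). Elements not listed fall back to 1.70.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}
_DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.capitalize(), _DEFAULT_VDW)


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, coordinates and derived flags."""

    element: str
    coord: np.ndarray  # shape (3,), A

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("atom coordinate must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)

    @property
    def is_heavy(self) -> bool:
        return self.element.capitalize() != "H"

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)


@dataclass
class Molecule:
    """A small molecule with an optional library of conformers.

    ``conformers[0]`` is the primary geometry; all conformers share the atom
    order and element sequence.  ``rotatable_bonds`` indexes into ``bonds``.
    """

    elements: list[str]
    conformers: list[np.ndarray]  # each (n_atoms, 3)
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    rotatable_bonds: list[int] = field(default_factory=list)
    name: str = "LIG"

    def __post_init__(self):
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        n = len(self.elements)
        for c in self.conformers:
            if c.shape != (n, 3):
                raise ValueError("conformer shape does not match atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.capitalize() != "H" for e in self.elements])

    @property
    def n_heavy(self) -> int:
        return int(self.heavy_mask.sum())

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([vdw_radius(e) for e in self.elements])

    @property
    def n_rotatable_bonds(self) -> int:
        return len(self.rotatable_bonds)

    @property
    def neighbor_atom(self) -> int:
        return neighbor_atom(self)

    def coords(self, conformer: int = 0) -> np.ndarray:
        return self.conformers[conformer]

    def heavy_centroid(self, conformer: int = 0) -> np.ndarray:
        return self.conformers[conformer][self.heavy_mask].mean(axis=0)


@dataclass
class Receptor:
    """A rigid receptor: heavy atoms with backbone/side-chain designation."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    backbone_mask: np.ndarray  # bool per atom
    atom_names: list[str] = field(default_factory=list)
    res_names: list[str] = field(default_factory=list)
    res_ids: list[int] = field(default_factory=list)
    chain_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.backbone_mask = np.asarray(self.backbone_mask, dtype=bool)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords shape does not match atom count")
        heavy = self.heavy_mask
        if np.any(self.backbone_mask & ~heavy):
            raise ValueError("backbone_mask may only flag heavy atoms")
        self._kdtree = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.capitalize() != "H" for e in self.elements])

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_mask]

    @property
    def backbone_heavy_coords(self) -> np.ndarray:
        return self.coords[self.backbone_mask]

    @property
    def heavy_vdw_radii(self) -> np.ndarray:
        return np.array(
            [vdw_radius(e) for e, h in zip(self.elements, self.heavy_mask) if h]
        )

    @property
    def center_of_mass(self) -> np.ndarray:
        # declared convention: unweighted heavy-atom centroid
        return self.heavy_coords.mean(axis=0)

    def kdtree(self):
        """Cached KD-tree over heavy-atom coordinates."""
        if self._kdtree is None:
            from scipy.spatial import cKDTree

            self._kdtree = cKDTree(self.heavy_coords)
        return self._kdtree


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: x -> R (x - pivot) + pivot + t."""

    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or abs(
            np.linalg.det(R) - 1.0
        ) > 1e-9:
            raise ValueError("rotation matrix is not proper orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``
        (both about the origin pivot)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class Pose:
    """One placement of a ligand conformer in the receptor frame."""

    molecule: Molecule
    conformer_index: int
    coords: np.ndarray  # (n_atoms, 3), receptor frame
    grid_score: float = np.nan
    fa_score: float = np.nan
    rmsd_to_native: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.molecule.n_atoms, 3):
            raise ValueError("pose coords do not match molecule atom count")

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.molecule.heavy_mask]

    def heavy_centroid(self) -> np.ndarray:
        return self.heavy_coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, **kw) -> "Pose":
        return replace(self, coords=np.asarray(coords, dtype=float), **kw)


def neighbor_atom(molecule: Molecule) -> int:
    """Index of the heavy atom closest to the heavy-atom geometric center.

    The "neighbor atom" is used as a cheap single-point probe of the scoring
    grid during translation moves.  Computed on conformer 0; ties broken by
    lowest atom index.  Invariant under rigid transforms of the molecule.
    """
    heavy = molecule.heavy_mask
    if not heavy.any():
        raise ValueError("molecule has no heavy atoms")
    coords = molecule.conformers[0]
    centroid = coords[heavy].mean(axis=0)
    d = np.linalg.norm(coords - centroid, axis=1)
    d[~heavy] = np.inf
    return int(np.argmin(d))  # argmin takes the first (lowest-index) minimum


def apply_transform(
    coords: np.ndarray, transform: RigidTransform, pivot: Sequence[float]
) -> np.ndarray:
    """Apply ``x -> R (x - pivot) + pivot + t`` to every coordinate row."""
    pivot = np.asarray(pivot, dtype=float)
    if pivot.shape != (3,):
        raise ValueError("pivot must be a 3-vector")
    return (coords - pivot) @ transform.rotation.T + pivot + transform.translation


def random_uniform_rotation(rng: np.random.Generator) -> RigidTransform:
    """A rotation drawn uniformly from SO(3) (random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return RigidTransform(Rotation.from_quat(q).as_matrix(), np.zeros(3))


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    if n == 0.0:
        return np.zeros(3)
    r = radius * rng.random() ** (1.0 / 3.0)
    return v * (r / n)


def random_small_perturbation(
    rng: np.random.Generator, max_trans: float, max_angle_deg: float
) -> RigidTransform:
    """A bounded rigid perturbation.

    Translation uniform in the ball of radius ``max_trans``; rotation about a
    uniformly random axis by an angle uniform in [0, ``max_angle_deg``].
    """
    if max_trans < 0:
        raise ValueError("max_trans must be >= 0")
    if not 0 <= max_angle_deg <= 360:
        raise ValueError("max_angle_deg must be in [0, 360]")
    t = _random_in_ball(rng, max_trans)
    axis = rng.normal(size=3)
    n = np.linalg.norm(axis)
    axis = axis / n if n > 0 else np.array([0.0, 0.0, 1.0])
    angle = np.deg2rad(max_angle_deg) * rng.random()
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    return RigidTransform(R, t)


def ligand_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation between two same-order coordinate sets.

    No superposition is performed: both sets live in the fixed receptor
    frame, so the value reflects the actual displacement of the ligand.
    Callers are expected to pass heavy-atom coordinates only.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def detect_rotatable_bonds(
    elements: Sequence[str], bonds: Sequence[tuple[int, int, int]]
) -> list[int]:
    """Detect rotatable bonds: acyclic single bonds between heavy atoms where
    each end has at least one other heavy neighbor (i.e. the bond is not
    terminal and torsion about it moves atoms)."""
    import networkx as nx

    heavy = [e.capitalize() != "H" for e in elements]
    g = nx.Graph()
    g.add_nodes_from(range(len(elements)))
    for i, j, _order in bonds:
        g.add_edge(i, j)
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add(frozenset((a, b)))

    def heavy_degree_excluding(i: int, j: int) -> int:
        return sum(1 for nb in g.neighbors(i) if nb != j and heavy[nb])

    out = []
    for idx, (i, j, order) in enumerate(bonds):
        if order != 1:
            continue
        if not (heavy[i] and heavy[j]):
            continue
        if frozenset((i, j)) in ring_edges:
            continue
        if heavy_degree_excluding(i, j) >= 1 and heavy_degree_excluding(j, i) >= 1:
            out.append(idx)
    return out
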