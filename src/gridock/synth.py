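"""Synthetic protein/ligand fixtures with known native poses.

Real benchmark sets cannot ship with a test suite, so this module builds
pseudo-receptors whose backbone heavy atoms line a pocket of controlled
shape around a ligand of controlled topology:

* ``rod_channel`` — a straight tube closed at one end, open at the other,
  around a rod-shaped ligand: the geometry where independent translate/
  rotate sampling struggles (the rod must be oriented before it can enter).
* ``bent_channel`` — the same tube construction following a bent ligand.
* ``imprint`` — a shell of receptor atoms at contact distance all around
  the ligand with one opening cone: a deep, specific pocket the docking
  algorithms should recover.
* ``open_shelf`` — a flat wall under the ligand only: a shallow site with
  weak orientation preference.

Wall atoms sit 3.0-4.0 A from the nearest native ligand atom — inside the
attractive band of the scoring grid and outside hard-sphere contact — so
every native pose is clash-free and reachable under the placement
algorithms' own acceptance rules.  All construction is deterministic given
the seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import GridManager, check_rotate_acceptance
from .model import Molecule, Pose, Receptor, detect_rotatable_bonds
from .refine import FaScoreParams, count_clashes

__all__ = [
    "LigandSpec",
    "SyntheticComplex",
    "make_synthetic_complex",
    "conformer_enumerate",
    "POCKET_KINDS",
]

POCKET_KINDS = ("rod_channel", "bent_channel", "imprint", "open_shelf")

_BOND_LENGTH = 1.5  # A, pseudo C-C
_WALL_RADIUS = 3.5  # A, wall distance from native ligand atoms
_CHANNEL_RADIUS = 4.2  # A, tube radius about the smoothed chain axis
_WALL_SPACING = 1.8  # A, between wall atoms
_JACKET_OFFSET = 2.2  # A, second wall layer standing in for the protein body
_RING_ATOMS = 10


@dataclass
class LigandSpec:
    """Shape and topology of a synthetic ligand."""

    n_atoms: int = 8
    shape: str = "rod"  # rod | bent | globular
    n_rotatable: int = 0  # 0-3
    jitter: float = 0.12  # A, per-atom asymmetry noise

    def __post_init__(self):
        if not 3 <= self.n_atoms <= 30:
            raise ValueError("n_atoms must be in [3, 30]")
        if self.shape not in ("rod", "bent", "globular"):
            raise ValueError(f"unknown ligand shape {self.shape!r}")
        if not 0 <= self.n_rotatable <= 3:
            raise ValueError("n_rotatable must be in [0, 3]")


@dataclass
class SyntheticComplex:
    """A pseudo-receptor, its ligand and the known native pose."""

    receptor: Receptor
    ligand: Molecule
    native_pose: Pose
    pocket_kind: str
    start_coord: np.ndarray
    seed: int
    ligand_spec: LigandSpec
    _grid_manager: Optional[GridManager] = field(default=None, repr=False)

    @property
    def native_heavy_coords(self) -> np.ndarray:
        return self.native_pose.heavy_coords

    def grid_manager(self, side: float = 10.0, spacing: float = 0.25,
                     translate_radius: float = 5.0) -> GridManager:
        """Default grid for this complex, centered on the start coordinate
        and auto-expanded so sampling moves are never clipped (cached)."""
        if self._grid_manager is None:
            lig = self.native_heavy_coords
            extent = float(
                np.linalg.norm(lig[:, None] - lig[None, :], axis=2).max()
            )
            # the start may sit away from the native pocket; cover both
            extent += 2.0 * float(
                np.linalg.norm(self.start_coord - lig.mean(axis=0))
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._grid_manager = GridManager.build(
                    self.receptor, self.start_coord, side, spacing,
                    ligand_extent=extent, translate_radius=translate_radius,
                )
        return self._grid_manager


# ---------------------------------------------------------------------------
# ligand construction

def _chain_coords(n: int, bend_at: Optional[int], rng: np.random.Generator,
                  jitter: float) -> np.ndarray:
    """Zig-zag carbon chain; optionally turned out of plane at ``bend_at``."""
    alpha = math.radians(35.26)  # half the tetrahedral angle complement
    step_even = _BOND_LENGTH * np.array(
        [math.cos(alpha), 0.0, math.sin(alpha)])
    step_odd = _BOND_LENGTH * np.array(
        [math.cos(alpha), 0.0, -math.sin(alpha)])
    # out-of-plane turn applied to all steps after the bend -> chiral L-shape
    turn = None
    if bend_at is not None:
        from scipy.spatial.transform import Rotation

        turn = Rotation.from_euler("zx", [75.0, 35.0], degrees=True).as_matrix()
    coords = [np.zeros(3)]
    for i in range(1, n):
        step = step_even if i % 2 == 1 else step_odd
        if turn is not None and i > bend_at:
            step = turn @ step
        coords.append(coords[-1] + step)
    coords = np.array(coords)
    if jitter > 0:
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    return coords - coords.mean(axis=0)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi * k), r * np.sin(phi * k), z])


def _globular_coords(n: int, rng: np.random.Generator,
                     jitter: float) -> np.ndarray:
    coords = [np.zeros(3)]
    shell_r = _BOND_LENGTH
    while len(coords) < n:
        remaining = n - len(coords)
        cap = max(6, int(4.0 * math.pi * shell_r ** 2 / (_BOND_LENGTH ** 2)))
        take = min(remaining, cap)
        coords.extend(shell_r * _fibonacci_sphere(take))
        shell_r += _BOND_LENGTH
    coords = np.array(coords[:n])
    if jitter > 0:
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    return coords - coords.mean(axis=0)


def make_ligand(spec: LigandSpec, rng: np.random.Generator,
                name: str = "LIG") -> Molecule:
    """Build a pseudo-ligand (all carbons) matching ``spec``.

    Rotatable-bond count is controlled through bond orders: the chosen
    internal chain bonds stay single, every other bond is marked double so
    the detection rule finds exactly ``spec.n_rotatable`` rotatable bonds.
    """
    n = spec.n_atoms
    if spec.shape == "globular":
        coords = _globular_coords(n, rng, spec.jitter)
        # spanning tree: each atom bonds to its nearest earlier atom
        bonds = []
        for i in range(1, n):
            d = np.linalg.norm(coords[:i] - coords[i], axis=1)
            bonds.append((int(np.argmin(d)), i, 2))
    else:
        # bend off-center: equal arms would leave a near-symmetry that maps
        # the flipped ligand onto its own imprint
        bend_at = max(2, n // 3) if spec.shape == "bent" else None
        coords = _chain_coords(n, bend_at, rng, spec.jitter)
        bonds = [(i, i + 1, 2) for i in range(n - 1)]

    degree = np.zeros(n, dtype=int)
    for i, j, _o in bonds:
        degree[i] += 1
        degree[j] += 1
    internal = [b for b, (i, j, _o) in enumerate(bonds)
                if degree[i] >= 2 and degree[j] >= 2]
    if spec.n_rotatable > len(internal):
        raise ValueError(
            f"ligand with {n} atoms cannot host {spec.n_rotatable} "
            "rotatable bonds")
    # spread the single bonds evenly along the chain
    chosen = [internal[int(round(t))] for t in
              np.linspace(0, len(internal) - 1, spec.n_rotatable)] \
        if spec.n_rotatable else []
    bonds = [(i, j, 1 if b in chosen else o)
             for b, (i, j, o) in enumerate(bonds)]

    mol = Molecule(elements=["C"] * n, conformers=[coords], bonds=bonds,
                   name=name)
    mol.rotatable_bonds = detect_rotatable_bonds(mol.elements, mol.bonds)
    if len(mol.rotatable_bonds) != spec.n_rotatable:
        raise RuntimeError("rotatable-bond construction failed")  # pragma: no cover
    return mol


# ---------------------------------------------------------------------------
# conformer enumeration

def _graph_distances_leq2(n_atoms: int, bonds) -> set[frozenset]:
    """Pairs of atoms separated by one or two bonds (1-2 and 1-3 pairs)."""
    adj = {i: set() for i in range(n_atoms)}
    for i, j, _o in bonds:
        adj[i].add(j)
        adj[j].add(i)
    close = set()
    for i in range(n_atoms):
        for j in adj[i]:
            close.add(frozenset((i, j)))
            for k in adj[j]:
                if k != i:
                    close.add(frozenset((i, k)))
    return close


def conformer_enumerate(molecule: Molecule, max_conformers: int = 100,
                        rng: Optional[np.random.Generator] = None) -> Molecule:
    """Enumerate torsion settings at 120-degree steps per rotatable bond.

    Self-clashing settings (a pair of atoms at least three bonds apart
    closer than 0.7 * the sum of their vdW radii) are dropped; the original
    geometry stays as conformer 0 and the remainder is uniformly subsampled
    down to ``max_conformers`` when necessary.  Bond lengths are exactly
    preserved: each torsion rigidly rotates one side of its bond.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if not molecule.rotatable_bonds:
        molecule.conformers = [molecule.conformers[0]]
        return molecule

    base = molecule.conformers[0]
    n = molecule.n_atoms
    adj = {i: set() for i in range(n)}
    for i, j, _o in molecule.bonds:
        adj[i].add(j)
        adj[j].add(i)

    def moving_side(i: int, j: int) -> list[int]:
        """Atoms on the j side when bond i-j is cut."""
        seen = {i, j}
        stack = [j]
        out = [j]
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
                    out.append(b)
        return out

    torsions = []
    for b in molecule.rotatable_bonds:
        i, j, _o = molecule.bonds[b]
        torsions.append((i, j, moving_side(i, j)))

    close_pairs = _graph_distances_leq2(n, molecule.bonds)
    radii = molecule.vdw_radii
    pair_idx = np.array(
        [(i, j) for i in range(n) for j in range(i + 1, n)
         if frozenset((i, j)) not in close_pairs]
    ).reshape(-1, 2)
    clash_cut = (0.7 * (radii[pair_idx[:, 0]] + radii[pair_idx[:, 1]])
                 if len(pair_idx) else None)

    from scipy.spatial.transform import Rotation

    conformers = []
    angles = (0.0, 120.0, 240.0)
    for setting in itertools.product(angles, repeat=len(torsions)):
        coords = base.copy()
        for (i, j, side), angle in zip(torsions, setting):
            if angle == 0.0:
                continue
            axis = coords[j] - coords[i]
            axis = axis / np.linalg.norm(axis)
            rot = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
            coords[side] = (coords[side] - coords[j]) @ rot.T + coords[j]
        if clash_cut is not None and len(pair_idx):
            d = np.linalg.norm(coords[pair_idx[:, 0]] - coords[pair_idx[:, 1]],
                               axis=1)
            if (d < clash_cut).any():
                if all(a == 0.0 for a in setting):  # pragma: no cover
                    raise ValueError("input geometry is self-clashing")
                continue
        conformers.append(coords)

    if len(conformers) > max_conformers:
        keep = rng.choice(len(conformers) - 1, size=max_conformers - 1,
                          replace=False) + 1
        conformers = [conformers[0]] + [conformers[i] for i in sorted(keep)]
    molecule.conformers = conformers
    return molecule


# ---------------------------------------------------------------------------
# receptor construction

def _resample_path(points: np.ndarray, spacing: float,
                   pre: float, post: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ``spacing``, extended by ``pre``/``post`` A
    beyond its ends (negative values truncate).  Returns (points, unit
    tangents)."""
    points = np.asarray(points, dtype=float)
    deltas = np.diff(points, axis=0)
    seg_len = np.linalg.norm(deltas, axis=1)
    t0 = deltas[0] / seg_len[0]
    t1 = deltas[-1] / seg_len[-1]
    if post < 0:
        if -post >= seg_len[-1]:
            raise ValueError("truncation longer than the final path segment")
        points = points.copy()
        points[-1] = points[-1] + post * t1
        post = 0.0
    rows = [points]
    if pre > 0:
        rows.insert(0, points[0][None, :] - pre * t0)
    if post > 0:
        rows.append(points[-1][None, :] + post * t1)
    ext = np.vstack(rows)
    deltas = np.diff(ext, axis=0)
    seg_len = np.linalg.norm(deltas, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    stations = np.arange(0.0, total + 1e-9, spacing)
    if total - stations[-1] > 0.25 * spacing:
        stations = np.append(stations, total)  # always cover the far end
    pts, tans = [], []
    for s in stations:
        k = min(np.searchsorted(cum, s, side="right") - 1, len(seg_len) - 1)
        frac = (s - cum[k]) / seg_len[k]
        pts.append(ext[k] + frac * deltas[k])
        tans.append(deltas[k] / seg_len[k])
    return np.array(pts), np.array(tans)


def _perp_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangent, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(tangent, ref)
    u /= np.linalg.norm(u)
    v = np.cross(tangent, u)
    return u, v


def _axis_path(lig_coords: np.ndarray,
               bend_at: Optional[int]) -> np.ndarray:
    """Smoothed path through a chain ligand: the least-squares axis for a
    rod, or two joined axes split at the bend atom for a bent chain.  The
    tube is built around this path rather than the raw zig-zag polyline, so
    ring orientations stay stable."""

    def segment_line(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = pts.mean(axis=0)
        _u, _s, vt = np.linalg.svd(pts - c)
        axis = vt[0]
        proj = (pts - c) @ axis
        # orient along increasing atom index
        if proj[-1] < proj[0]:
            axis = -axis
            proj = -proj
        return c + proj.min() * axis, c + proj.max() * axis

    if bend_at is None:
        p0, p1 = segment_line(lig_coords)
        return np.array([p0, p1])
    a0, a1 = segment_line(lig_coords[: bend_at + 1])
    b0, b1 = segment_line(lig_coords[bend_at:])
    elbow = 0.5 * (a1 + b0)
    return np.array([a0, elbow, b1])


def _tube_wall(path: np.ndarray, radius: float, closed_pre: float,
               open_post: float) -> tuple[np.ndarray, np.ndarray]:
    """Rings of wall atoms around the ligand path; a disc caps the closed
    end.  Returns (wall points, open-end direction).

    Each ring carries a second, "jacket" layer ``_JACKET_OFFSET`` further
    out.  The jacket stands in for the protein body behind the binding-site
    surface: its repulsive shells block the exterior face of the wall, so
    the attractive corridor seen by the sampler is the pocket interior, not
    both sides of an isolated atom sheet.
    """
    pts, tans = _resample_path(path, _WALL_SPACING, closed_pre, open_post)
    wall = []
    for ring, (p, t) in enumerate(zip(pts, tans)):
        u, v = _perp_frame(t)
        offset = (ring % 2) * math.pi / _RING_ATOMS  # stagger rings
        for layer_r, count in ((radius, _RING_ATOMS),
                               (radius + _JACKET_OFFSET,
                                _RING_ATOMS + 6)):
            for a in range(count):
                ang = 2 * math.pi * a / count + offset
                wall.append(p + layer_r * (math.cos(ang) * u
                                           + math.sin(ang) * v))
    # doubled, staggered rim at the mouth: full azimuthal repulsive
    # coverage at the pocket lip keeps the all-attractive region confined
    # to the bore instead of leaking around the entrance
    u, v = _perp_frame(tans[-1])
    for layer_r, count in ((radius, _RING_ATOMS),
                           (radius + _JACKET_OFFSET, _RING_ATOMS + 6)):
        for a in range(count):
            ang = 2 * math.pi * (a + 0.5) / count
            wall.append(pts[-1] + layer_r * (math.cos(ang) * u
                                             + math.sin(ang) * v))
    # closed-end cap: concentric rings in the plane normal to the path,
    # duplicated one jacket offset further back
    u, v = _perp_frame(tans[0])
    for back in (0.0, _JACKET_OFFSET):
        cap_center = pts[0] - back * tans[0]
        wall.append(cap_center.copy())
        for r, count in ((1.75, 6), (3.5, 10)):
            for a in range(count):
                ang = 2 * math.pi * a / count
                wall.append(cap_center + r * (math.cos(ang) * u
                                              + math.sin(ang) * v))
    return np.array(wall), tans[-1]


def _imprint_wall(lig_coords: np.ndarray,
                  open_dir: np.ndarray) -> np.ndarray:
    """Shell of wall atoms at contact distance around the ligand, with an
    opening cone along ``open_dir``."""
    centroid = lig_coords.mean(axis=0)
    dirs = _fibonacci_sphere(42)
    layers = []
    for radius in (_WALL_RADIUS, _WALL_RADIUS + _JACKET_OFFSET):
        candidates = []
        for atom in lig_coords:
            for d in dirs:
                p = atom + radius * d
                out_dir = p - centroid
                out_dir /= np.linalg.norm(out_dir)
                if np.dot(out_dir, open_dir) > math.cos(math.radians(50.0)):
                    continue  # leave the entrance open
                dmin = np.linalg.norm(lig_coords - p, axis=1).min()
                if dmin < radius - 0.2:
                    continue  # would crowd another ligand atom
                candidates.append((dmin, p))
        # deterministic greedy thinning, closest-to-ligand first
        candidates.sort(key=lambda t: (round(t[0], 6),
                                       tuple(np.round(t[1], 6))))
        kept: list[np.ndarray] = []
        for _dmin, p in candidates:
            if all(np.linalg.norm(p - q) >= 1.6 for q in kept):
                kept.append(p)
        layers.append(np.array(kept))
    return np.vstack(layers)


def _shelf_wall(lig_coords: np.ndarray) -> np.ndarray:
    z = lig_coords[:, 2].min() - _WALL_RADIUS
    x0, x1 = lig_coords[:, 0].min() - 5.0, lig_coords[:, 0].max() + 5.0
    y0, y1 = lig_coords[:, 1].min() - 5.0, lig_coords[:, 1].max() + 5.0
    xs = np.arange(x0, x1 + 1e-9, _WALL_SPACING)
    ys = np.arange(y0, y1 + 1e-9, _WALL_SPACING)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    planes = [np.column_stack([gx.ravel(), gy.ravel(),
                               np.full(gx.size, z - back)])
              for back in (0.0, _JACKET_OFFSET)]
    return np.vstack(planes)


_BB_NAMES = ("N", "CA", "C", "O")
_BB_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _receptor_from_wall(wall: np.ndarray) -> Receptor:
    n = wall.shape[0]
    names = [_BB_NAMES[i % 4] for i in range(n)]
    return Receptor(
        elements=[_BB_ELEMENTS[nm] for nm in names],
        coords=wall,
        backbone_mask=np.ones(n, dtype=bool),
        atom_names=names,
        res_names=["GLY"] * n,
        res_ids=[i // 4 + 1 for i in range(n)],
        chain_ids=["A"] * n,
    )


def make_synthetic_complex(pocket_kind: str, ligand_spec: LigandSpec,
                           seed: int, max_conformers: int = 27,
                           start_offset: float = 2.5) -> SyntheticComplex:
    """Build a deterministic pocket/ligand pair with a known native pose.

    The native ligand sits centered at the origin; the start coordinate is
    offset ``start_offset`` (< 5) A from the native centroid in a random
    but seed-determined direction, emulating a user-supplied approximate
    binding-site center: placement begins near, but never at, the answer.
    """
    if pocket_kind not in POCKET_KINDS:
        raise ValueError(f"unknown pocket kind {pocket_kind!r}")
    rng = np.random.default_rng(seed)
    ligand = make_ligand(ligand_spec, rng)
    if ligand_spec.n_rotatable:
        ligand = conformer_enumerate(ligand, max_conformers=max_conformers,
                                     rng=rng)
    native = ligand.conformers[0]  # heavy centroid at origin by construction
    heavy = ligand.heavy_mask
    lig_heavy = native[heavy]

    if pocket_kind in ("rod_channel", "bent_channel"):
        expected = "rod" if pocket_kind == "rod_channel" else "bent"
        if ligand_spec.shape != expected:
            raise ValueError(
                f"{pocket_kind} expects a {expected}-shaped ligand")
        bend_at = max(2, ligand_spec.n_atoms // 3) if expected == "bent" \
            else None
        path = _axis_path(lig_heavy, bend_at)
        # the tube ends at the ligand's far end: the native pose fills the
        # pocket, with its outermost atom sitting in the mouth plane
        wall, open_dir = _tube_wall(path, _CHANNEL_RADIUS,
                                    closed_pre=_WALL_RADIUS,
                                    open_post=0.0)
    elif pocket_kind == "imprint":
        open_dir = np.array([1.0, 0.0, 0.0])
        wall = _imprint_wall(lig_heavy, open_dir)
    else:  # open_shelf
        open_dir = np.array([0.0, 0.0, 1.0])
        wall = _shelf_wall(lig_heavy)

    # hard guarantee: no wall atom inside steric contact of the native pose
    dmin = np.linalg.norm(
        wall[:, None, :] - lig_heavy[None, :, :], axis=2).min(axis=1)
    wall = wall[dmin >= 3.0]

    receptor = _receptor_from_wall(wall)
    # starting coordinate: the user's rough guess at the binding-site
    # center — the native centroid displaced by ``start_offset`` in a
    # seed-determined random direction (it may fall inside the pocket,
    # against a wall, or just outside the mouth, as a hand-picked site
    # center would)
    start_dir = rng.normal(size=3)
    start_dir /= np.linalg.norm(start_dir)
    start = lig_heavy.mean(axis=0) + start_offset * start_dir

    native_pose = Pose(molecule=ligand, conformer_index=0,
                       coords=native.copy(), grid_score=np.nan,
                       provenance={"algorithm": "native", "seed": seed})
    cx = SyntheticComplex(
        receptor=receptor, ligand=ligand, native_pose=native_pose,
        pocket_kind=pocket_kind, start_coord=start, seed=seed,
        ligand_spec=ligand_spec,
    )

    params = FaScoreParams()
    n_clash = count_clashes(lig_heavy, ligand.vdw_radii[heavy], receptor,
                            params)
    if n_clash > 0:
        raise ValueError(
            f"infeasible fixture: native pose has {n_clash} clashes")
    if pocket_kind == "imprint":
        ok, diag = check_rotate_acceptance(
            cx.grid_manager().primary, lig_heavy)
        if not ok:
            raise ValueError(
                "infeasible imprint fixture: native pose fails the "
                f"orientation acceptance rule ({diag})")
    return cx
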