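"""Initial ligand placement: legacy TransRot and grid-scored Transform.

TransRot runs three independent stages — Translate (accept the first of up
to 50 random offsets whose neighbor-atom cell is attractive or neutral),
Rotate (accumulate a diverse set of non-clashing reorientations, pick one at
random), Slide Together (advance toward the receptor center of mass until
just before steric contact).

Transform replaces all three with a single Metropolis Monte Carlo walk over
combined translation/rotation/conformer-swap moves scored on the grid; after
a fixed cycle budget the best-scoring accepted pose is kept.  Poses are
plain Cartesian coordinate lists updated by rotation/translation matrices,
which is what makes 500 grid-scored cycles cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .grid import ScoringGrid, check_rotate_acceptance, score_ligand, score_point
from .model import (
    Molecule,
    Pose,
    Receptor,
    ligand_rmsd,
)

__all__ = [
    "PlacementConfig",
    "McTrajectory",
    "translate_step",
    "build_orientation_set",
    "rotate_step",
    "slide_together",
    "transrot_place",
    "metropolis_accept",
    "transform_place",
]


@dataclass
class PlacementConfig:
    """Knobs for both placement algorithms (distances in A, angles in deg)."""

    start_coord: np.ndarray = None  # required: ligand centroid start, receptor frame
    translate_radius: float = 5.0
    translate_attempts: int = 50
    rotate_attempts: int = 500
    diversity_base: int = 5
    diversity_coeff_per_rotbond: int = 5
    rmsd_diversity_coeff: float = 0.65
    transform_cycles: int = 500
    mc_temperature: float = 1.0
    per_move_max_trans: float = 0.5
    per_move_max_angle: float = 30.0
    conformer_swap_prob: float = 0.1
    box_radius: Optional[float] = None  # default: translate_radius
    seed: int = 0

    def __post_init__(self):
        if self.start_coord is not None:
            self.start_coord = np.asarray(self.start_coord, dtype=float)
        if self.box_radius is None:
            self.box_radius = self.translate_radius
        for name in ("translate_attempts", "rotate_attempts", "transform_cycles",
                     "diversity_base", "diversity_coeff_per_rotbond"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.conformer_swap_prob <= 1.0:
            raise ValueError("conformer_swap_prob must be in [0, 1]")
        if self.mc_temperature <= 0:
            raise ValueError("mc_temperature must be positive")

    def diverse_set_size(self, n_rotatable_bonds: int) -> int:
        """Target Rotate-step set size: max(base, coeff * rotatable bonds)."""
        return max(self.diversity_base,
                   self.diversity_coeff_per_rotbond * n_rotatable_bonds)

    def rmsd_diversity_threshold(self, n_heavy: int) -> float:
        """Minimum pairwise RMSD between diverse orientations (A)."""
        return self.rmsd_diversity_coeff * math.sqrt(n_heavy)


@dataclass
class McTrajectory:
    """Per-cycle diagnostics of a Metropolis run."""

    move_types: list[str] = field(default_factory=list)
    proposed_scores: list[float] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)
    current_scores: list[float] = field(default_factory=list)
    state_coords: list[np.ndarray] = field(default_factory=list)  # heavy atoms
    best_score: float = np.inf
    best_cycle: int = -1
    acceptance_counts: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.accepted)


# ---------------------------------------------------------------------------
# fast primitives (inner-loop versions that avoid object construction)

def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle in radians."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    t = 1.0 - c
    return np.array([
        [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
        [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
        [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
    ])


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(3)
    return _random_unit_vector(rng) * (radius * rng.random() ** (1.0 / 3.0))


def _uniform_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform SO(3) sample via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# TransRot stages

def translate_step(pose: Pose, grid: ScoringGrid, cfg: PlacementConfig,
                   rng: np.random.Generator) -> Pose:
    """Translate stage: random offsets until the neighbor atom lands well.

    Up to ``cfg.translate_attempts`` uniform offsets within the
    ``cfg.translate_radius`` ball of the *starting* position are proposed;
    the first whose neighbor-atom cell scores attractive (-1) or neutral (0)
    is accepted and the stage stops.  If none is accepted the last proposal
    is returned with ``provenance['translate_failed'] = True``.
    """
    nbr = pose.molecule.neighbor_atom
    base = pose.coords
    coords = base
    accepted = False
    attempts = 0
    for attempts in range(1, cfg.translate_attempts + 1):
        offset = _random_in_ball(rng, cfg.translate_radius)
        coords = base + offset
        if score_point(grid, coords[nbr]) <= 0:
            accepted = True
            break
    prov = dict(pose.provenance)
    prov.update(translate_attempts=attempts, translate_failed=not accepted)
    return pose.with_coords(coords, provenance=prov, grid_score=np.nan)


def build_orientation_set(pose: Pose, grid: ScoringGrid,
                          cfg: PlacementConfig,
                          rng: np.random.Generator) -> list[np.ndarray]:
    """Accumulate the Rotate stage's diverse set of acceptable orientations.

    Returns full-coordinate arrays; see :func:`rotate_step` for the
    acceptance and diversity rules.
    """
    mol = pose.molecule
    heavy = mol.heavy_mask
    target = cfg.diverse_set_size(mol.n_rotatable_bonds)
    threshold = cfg.rmsd_diversity_threshold(mol.n_heavy)
    centroid = pose.heavy_coords.mean(axis=0)
    base = pose.coords - centroid

    members: list[np.ndarray] = []
    members_heavy: list[np.ndarray] = []
    for _ in range(cfg.rotate_attempts):
        R = _uniform_rotation_matrix(rng)
        cand = base @ R.T + centroid
        cand_heavy = cand[heavy]
        ok, _diag = check_rotate_acceptance(grid, cand_heavy)
        if not ok:
            continue
        if any(ligand_rmsd(cand_heavy, mh) <= threshold
               for mh in members_heavy):
            continue
        members.append(cand)
        members_heavy.append(cand_heavy)
        if len(members) >= target:
            break
    return members


def rotate_step(pose: Pose, grid: ScoringGrid, cfg: PlacementConfig,
                rng: np.random.Generator) -> Pose:
    """Rotate stage: build a diverse set of non-clashing orientations.

    Proposes up to ``cfg.rotate_attempts`` uniform reorientations about the
    heavy-atom centroid.  A proposal joins the set iff no heavy atom is in a
    repulsive cell, >=85% are in attractive cells, and its RMSD to every
    member already accepted exceeds 0.65*sqrt(n_heavy).  The stage stops at
    the attempt cap or a full set, then returns one member uniformly at
    random.  An empty set returns the input pose flagged as failed.
    """
    members = build_orientation_set(pose, grid, cfg, rng)
    prov = dict(pose.provenance)
    prov.update(rotate_set_size=len(members), rotate_failed=not members)
    if not members:
        return replace(pose, provenance=prov)
    choice = int(rng.integers(len(members)))
    return pose.with_coords(members[choice], provenance=prov)


def slide_together(pose: Pose, receptor: Receptor, fa_params, step: float = 0.1,
                   count_clashes=None) -> Pose:
    """Slide the ligand toward the receptor center of mass until contact.

    Repeats ``step``-A translations along the centroid->COM direction while
    the hard-sphere clash count stays zero, stopping just before the first
    clashing step or once the centroid is within one step of the COM.
    """
    if count_clashes is None:
        from .refine import count_clashes
    if step <= 0:
        raise ValueError("step must be positive")
    heavy = pose.molecule.heavy_mask
    radii = pose.molecule.vdw_radii[heavy]
    coords = pose.coords.copy()
    com = receptor.center_of_mass

    prov = dict(pose.provenance)
    if count_clashes(coords[heavy], radii, receptor, fa_params) > 0:
        prov.update(slide_steps=0, slide_entry_clash=True)
        return replace(pose, provenance=prov)

    centroid = coords[heavy].mean(axis=0)
    dist = float(np.linalg.norm(com - centroid))
    max_steps = int(dist / step) + 1
    direction = (com - centroid) / dist if dist > 1e-12 else np.zeros(3)
    taken = 0
    for _ in range(max_steps):
        if np.linalg.norm(com - coords[heavy].mean(axis=0)) <= step:
            break
        trial = coords + step * direction
        if count_clashes(trial[heavy], radii, receptor, fa_params) > 0:
            break
        coords = trial
        taken += 1
    prov.update(slide_steps=taken, slide_entry_clash=False)
    return pose.with_coords(coords, provenance=prov)


def transrot_place(molecule: Molecule, receptor: Receptor, grid: ScoringGrid,
                   cfg: PlacementConfig, rng: np.random.Generator,
                   fa_params=None) -> tuple[Pose, list[np.ndarray]]:
    """Full TransRot placement: Translate -> Rotate -> Slide Together.

    Returns the final pose plus the list of per-stage heavy-atom coordinate
    snapshots (one state after each stage) for sampling-efficiency analysis.
    Deterministic given the rng state.
    """
    if fa_params is None:
        from .refine import FaScoreParams
        fa_params = FaScoreParams()
    start = np.asarray(cfg.start_coord, dtype=float)
    conf = molecule.coords(0)
    centered = conf - molecule.heavy_centroid(0)
    # arbitrary initial orientation: the conformer frame carries no
    # information about the receptor frame
    coords = centered @ _uniform_rotation_matrix(rng).T + start
    pose = Pose(molecule=molecule, conformer_index=0, coords=coords,
                provenance={"algorithm": "transrot"})

    states = []
    pose = translate_step(pose, grid, cfg, rng)
    states.append(pose.heavy_coords.copy())
    pose = rotate_step(pose, grid, cfg, rng)
    states.append(pose.heavy_coords.copy())
    pose = slide_together(pose, receptor, fa_params)
    states.append(pose.heavy_coords.copy())

    score, _ = score_ligand(grid, pose.heavy_coords)
    pose.grid_score = score
    pose.provenance["failed"] = bool(
        pose.provenance.get("translate_failed") or pose.provenance.get("rotate_failed")
    )
    return pose, states


# ---------------------------------------------------------------------------
# Transform: Metropolis Monte Carlo on the grid

def metropolis_accept(delta_score: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: always accept downhill, exp(-delta/T) uphill."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_score <= 0:
        return True
    if np.isinf(delta_score):
        return False
    return rng.random() < math.exp(-delta_score / temperature)


def transform_place(molecule: Molecule, receptor: Receptor, grid: ScoringGrid,
                    cfg: PlacementConfig, rng: np.random.Generator,
                    record_states: bool = True) -> tuple[Pose, McTrajectory]:
    """Grid-scored Metropolis Monte Carlo placement.

    The ligand starts as conformer 0 with its heavy-atom centroid at
    ``cfg.start_coord`` in a uniformly random orientation.  Each of
    ``cfg.transform_cycles`` cycles proposes either a conformer swap (with
    probability ``conformer_swap_prob`` when a library is present) or a
    combined random translation/rotation; proposals placing any heavy atom
    outside the grid or the neighbor atom beyond ``box_radius`` of the start
    score +inf and are always rejected.  The Metropolis criterion drives
    acceptance on the grid score; the best-scoring accepted state is
    returned.  The receptor is rigid throughout.
    """
    heavy = molecule.heavy_mask
    nbr = molecule.neighbor_atom
    # neighbor atom position within the heavy-atom subset
    nbr_heavy = int(np.flatnonzero(heavy).tolist().index(nbr))
    start = np.asarray(cfg.start_coord, dtype=float)
    n_conf = molecule.n_conformers
    swaps_on = n_conf > 1 and cfg.conformer_swap_prob > 0

    # local aliases for the inner loop
    origin = grid.origin
    spacing = grid.spacing
    dims = np.array(grid.values.shape)
    values = grid.values
    box_r2 = float(cfg.box_radius) ** 2

    # conformer heavy coords centered on their own heavy centroid
    conf_heavy = [molecule.conformers[k][heavy] for k in range(n_conf)]
    conf_centered = [c - c.mean(axis=0) for c in conf_heavy]
    conf_full_centered = [
        molecule.conformers[k] - conf_heavy[k].mean(axis=0) for k in range(n_conf)
    ]

    def grid_score_of(heavy_coords: np.ndarray) -> float:
        d = heavy_coords[nbr_heavy] - start
        if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] > box_r2:
            return np.inf
        idx = np.floor((heavy_coords - origin) / spacing).astype(np.int64)
        if ((idx < 0) | (idx >= dims)).any():
            return np.inf
        return float(values[idx[:, 0], idx[:, 1], idx[:, 2]].sum())

    # state: conformer index k, cumulative rotation R, heavy centroid c
    k = 0
    R = _uniform_rotation_matrix(rng)
    c = start.copy()
    cur_heavy = conf_centered[k] @ R.T + c
    cur_score = grid_score_of(cur_heavy)

    traj = McTrajectory()
    best = None  # (score, k, R, c)
    if np.isfinite(cur_score):
        best = (cur_score, k, R.copy(), c.copy())
        traj.best_score = cur_score
        traj.best_cycle = 0

    temperature = cfg.mc_temperature
    max_trans = cfg.per_move_max_trans
    max_angle = math.radians(cfg.per_move_max_angle)
    n_accept = {"perturb": 0, "conformer_swap": 0}
    n_total = {"perturb": 0, "conformer_swap": 0}

    for cycle in range(cfg.transform_cycles):
        if swaps_on and rng.random() < cfg.conformer_swap_prob:
            move = "conformer_swap"
            new_k = int(rng.integers(n_conf))
            new_R = R
            new_c = c
        else:
            move = "perturb"
            new_k = k
            axis = _random_unit_vector(rng)
            angle = max_angle * rng.random()
            Rp = _rotation_about_axis(axis, angle)
            new_R = Rp @ R
            new_c = c + _random_in_ball(rng, max_trans)
        prop_heavy = conf_centered[new_k] @ new_R.T + new_c
        prop_score = grid_score_of(prop_heavy)

        delta = prop_score - cur_score
        if np.isnan(delta):  # inf - inf: both out of bounds, treat as uphill
            delta = np.inf
        accept = metropolis_accept(delta, temperature, rng)
        n_total[move] += 1
        if accept:
            k = new_k
            R = new_R
            c = new_c
            cur_heavy = prop_heavy
            cur_score = prop_score
            n_accept[move] += 1
            # ties update too: the binary grid is piecewise constant, so the
            # optimum is typically a plateau; keeping the most recent
            # equal-best state lets the walk diffuse across it instead of
            # pinning the first edge encountered
            if np.isfinite(cur_score) and (best is None or cur_score <= best[0]):
                best = (cur_score, k, R.copy(), c.copy())
                traj.best_score = cur_score
                traj.best_cycle = cycle + 1

        traj.move_types.append(move)
        traj.proposed_scores.append(prop_score)
        traj.accepted.append(accept)
        traj.current_scores.append(cur_score)
        if record_states:
            traj.state_coords.append(cur_heavy)

    traj.acceptance_counts = {
        m: {"accepted": n_accept[m], "proposed": n_total[m]} for m in n_accept
    }

    prov = {"algorithm": "transform", "cycles": cfg.transform_cycles}
    if best is None:
        prov["failed"] = True
        coords = conf_full_centered[0] @ R.T + start
        pose = Pose(molecule=molecule, conformer_index=0, coords=coords,
                    grid_score=np.inf, provenance=prov)
        return pose, traj

    b_score, b_k, b_R, b_c = best
    prov["failed"] = False
    prov["best_cycle"] = traj.best_cycle
    coords = conf_full_centered[b_k] @ b_R.T + b_c
    pose = Pose(molecule=molecule, conformer_index=b_k, coords=coords,
                grid_score=b_score, provenance=prov)
    return pose, traj
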