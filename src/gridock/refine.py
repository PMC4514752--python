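"""Atomic-detail refinement on a rigid receptor with a surrogate score.

The full-atom score used here is a deliberately simple, continuous
pair-potential over ligand/receptor heavy-atom pairs:

    sum_pairs [ w_rep * max(0, (r_i + r_j - tol) - d)^2
                - w_atr * triangle(d; contact = r_i + r_j, width) ]

i.e. a quadratic soft repulsion inside the tolerance-shrunk contact distance
and a triangular attraction well peaking at contact.  It is zero at full
separation, continuous in the coordinates, and cheap enough to evaluate
thousands of times per pose, which is all the refinement schedules need.

Two schedules are provided.  MIN re-selects the best library conformer at
the current placement and runs one rigid-body minimization.  MCM alternates
conformer-reselection/minimization steps with small random perturbations
(0.1 A / 20 deg) over six steps, keeps the best of the six, and finishes
with a final minimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Molecule, Pose, Receptor, random_small_perturbation

__all__ = [
    "FaScoreParams",
    "RefinementConfig",
    "count_clashes",
    "fa_score",
    "rigid_minimize",
    "refine_min",
    "refine_mcm",
]


@dataclass
class FaScoreParams:
    """Parameters of the surrogate full-atom pair score (distances in A)."""

    clash_tolerance: float = 0.6
    attr_well_width: float = 1.5
    w_rep: float = 1.0
    w_atr: float = 0.25

    def __post_init__(self):
        for name in ("clash_tolerance", "attr_well_width", "w_rep", "w_atr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RefinementConfig:
    """Schedule parameters for the MIN and MCM refinement protocols."""

    method: str = "min"  # "min" or "mcm"
    mcm_steps: int = 6
    perturb_trans: float = 0.1  # A
    perturb_angle: float = 20.0  # deg
    min_max_iter: int = 60
    min_initial_trans_step: float = 0.25  # A
    min_initial_rot_step: float = 0.1  # rad
    min_tol: float = 0.01  # A / rad step size at convergence

    def __post_init__(self):
        if self.method not in ("min", "mcm"):
            raise ValueError("method must be 'min' or 'mcm'")
        if self.mcm_steps % 2 != 0:
            raise ValueError("mcm_steps must be even (perturb/minimize alternation)")


def count_clashes(lig_heavy_coords: np.ndarray, lig_radii: np.ndarray,
                  receptor: Receptor, params: FaScoreParams) -> int:
    """Number of ligand/receptor heavy-atom pairs closer than contact - tol.

    Uses the receptor KD-tree so the cost scales with actual contacts rather
    than all pairs.
    """
    tree = receptor.kdtree()
    rec_radii = receptor.heavy_vdw_radii
    max_cut = float(lig_radii.max() + rec_radii.max() - params.clash_tolerance)
    n = 0
    neighborhoods = tree.query_ball_point(lig_heavy_coords, r=max_cut)
    rec_coords = receptor.heavy_coords
    for i, idxs in enumerate(neighborhoods):
        if not idxs:
            continue
        idxs = np.asarray(idxs)
        d = np.linalg.norm(rec_coords[idxs] - lig_heavy_coords[i], axis=1)
        cut = lig_radii[i] + rec_radii[idxs] - params.clash_tolerance
        n += int((d < cut).sum())
    return n


def fa_score(lig_heavy_coords: np.ndarray, lig_radii: np.ndarray,
             receptor: Receptor, params: FaScoreParams) -> float:
    """Surrogate full-atom score: soft repulsion plus triangular contact well."""
    rec_coords = receptor.heavy_coords
    rec_radii = receptor.heavy_vdw_radii
    diff = lig_heavy_coords[:, None, :] - rec_coords[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    contact = lig_radii[:, None] + rec_radii[None, :]
    rep = np.maximum(0.0, (contact - params.clash_tolerance) - d)
    atr = np.maximum(0.0, 1.0 - np.abs(d - contact) / params.attr_well_width)
    return float(params.w_rep * (rep ** 2).sum() - params.w_atr * atr.sum())


def pose_fa_score(pose: Pose, receptor: Receptor, params: FaScoreParams) -> float:
    heavy = pose.molecule.heavy_mask
    return fa_score(pose.coords[heavy], pose.molecule.vdw_radii[heavy],
                    receptor, params)


# 12 probe directions of the 6-DOF pattern search: +/- each translation and
# rotation axis.
_PROBES = np.vstack([np.eye(6), -np.eye(6)])


def rigid_minimize(pose: Pose, receptor: Receptor, params: FaScoreParams,
                   cfg: Optional[RefinementConfig] = None) -> Pose:
    """Derivative-free rigid-body (6-DOF) local minimization of the score.

    A pattern search over translation and rotation about the heavy-atom
    centroid: probe +/- steps along each axis, move greedily while any probe
    improves, halve the steps otherwise, stop at the iteration cap or once
    both steps fall below the tolerance.  The returned score never exceeds
    the input score.
    """
    cfg = cfg or RefinementConfig()
    mol = pose.molecule
    heavy = mol.heavy_mask
    radii = mol.vdw_radii[heavy]
    pivot = pose.coords[heavy].mean(axis=0)
    base = pose.coords - pivot

    def coords_of(p: np.ndarray) -> np.ndarray:
        Rm = Rotation.from_rotvec(p[3:]).as_matrix()
        return base @ Rm.T + pivot + p[:3]

    def score_of(p: np.ndarray) -> float:
        c = coords_of(p)
        return fa_score(c[heavy], radii, receptor, params)

    p = np.zeros(6)
    best = score_of(p)
    t_step, r_step = cfg.min_initial_trans_step, cfg.min_initial_rot_step
    for _ in range(cfg.min_max_iter):
        steps = np.array([t_step] * 3 + [r_step] * 3)
        improved = False
        for probe in _PROBES:
            q = p + probe * steps
            s = score_of(q)
            if s < best - 1e-12:
                p, best = q, s
                improved = True
        if not improved:
            t_step *= 0.5
            r_step *= 0.5
            if t_step < cfg.min_tol and r_step < cfg.min_tol:
                break
    return pose.with_coords(coords_of(p), fa_score=best)


def _best_conformer_at(pose: Pose, receptor: Receptor,
                       params: FaScoreParams) -> Pose:
    """Re-select the library conformer scoring best at the current placement.

    Each conformer is placed by least-squares (Kabsch) superposition of its
    heavy atoms onto the current pose, so the placement changes as little as
    the new internal geometry allows; the argmin conformer wins.  With a
    single conformer this is the identity.
    """
    mol = pose.molecule
    if mol.n_conformers == 1:
        s = pose_fa_score(pose, receptor, params)
        return replace(pose, fa_score=s)
    heavy = mol.heavy_mask
    radii = mol.vdw_radii[heavy]
    cur_heavy = pose.coords[heavy]
    cur_centroid = cur_heavy.mean(axis=0)
    best_pose, best_score = None, np.inf
    for k in range(mol.n_conformers):
        conf = mol.conformers[k]
        conf_heavy = conf[heavy]
        conf_centroid = conf_heavy.mean(axis=0)
        with warnings.catch_warnings():
            # collinear ligands leave one rotational DOF free; any optimal
            # rotation is acceptable here
            warnings.simplefilter("ignore", UserWarning)
            rot, _rssd = Rotation.align_vectors(cur_heavy - cur_centroid,
                                                conf_heavy - conf_centroid)
        Rm = rot.as_matrix()
        coords = (conf - conf_centroid) @ Rm.T + cur_centroid
        s = fa_score(coords[heavy], radii, receptor, params)
        if s < best_score:
            best_score = s
            best_pose = pose.with_coords(coords, conformer_index=k,
                                         fa_score=s)
    return best_pose


def refine_min(pose: Pose, receptor: Receptor, params: FaScoreParams,
               cfg: Optional[RefinementConfig] = None) -> Pose:
    """MIN refinement: one conformer re-selection, then rigid minimization."""
    cfg = cfg or RefinementConfig(method="min")
    return rigid_minimize(_best_conformer_at(pose, receptor, params),
                          receptor, params, cfg)


def refine_mcm(pose: Pose, receptor: Receptor, params: FaScoreParams,
               cfg: Optional[RefinementConfig] = None,
               rng: Optional[np.random.Generator] = None) -> Pose:
    """MCM refinement: six alternating steps, keep the best, minimize last.

    Odd steps re-select the conformer and minimize; even steps apply a small
    random rigid perturbation (0.1 A translation, up to 20 deg rotation).
    The pose recorded after each step competes; the best of the six receives
    a final rigid minimization.
    """
    cfg = cfg or RefinementConfig(method="mcm")
    rng = rng if rng is not None else np.random.default_rng(0)
    heavy = pose.molecule.heavy_mask
    radii = pose.molecule.vdw_radii[heavy]

    current = pose
    recorded: list[Pose] = []
    for step in range(1, cfg.mcm_steps + 1):
        if step % 2 == 1:
            current = rigid_minimize(
                _best_conformer_at(current, receptor, params), receptor,
                params, cfg)
        else:
            perturb = random_small_perturbation(
                rng, cfg.perturb_trans, cfg.perturb_angle)
            pivot = current.coords[heavy].mean(axis=0)
            coords = ((current.coords - pivot) @ perturb.rotation.T
                      + pivot + perturb.translation)
            s = fa_score(coords[heavy], radii, receptor, params)
            current = current.with_coords(coords, fa_score=s)
        recorded.append(current)

    best = min(recorded, key=lambda p: p.fa_score)
    out = rigid_minimize(best, receptor, params, cfg)
    prov = dict(pose.provenance)
    prov["refinement"] = "mcm"
    out.provenance = prov
    return out
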