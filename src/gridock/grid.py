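"""Binary attractive/repulsive scoring grids and the grid manager.

The classic low-resolution grid marks a cell +1 (repulsive) when its center
lies within 2.25 A of any backbone heavy atom, else -1 (attractive) when it
lies 2.25-4.75 A from any receptor heavy atom, else 0.  Repulsive takes
precedence where shells overlap.  Cells are categorical, so lookup is
nearest-cell (floor), never interpolated.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import Receptor

__all__ = [
    "OUT_OF_GRID",
    "ScoringGrid",
    "GridManager",
    "build_classic_grid",
    "score_point",
    "score_ligand",
    "check_rotate_acceptance",
    "REPULSIVE_RADIUS",
    "ATTRACTIVE_MIN",
    "ATTRACTIVE_MAX",
]

#: Sentinel returned by :func:`score_point` for coordinates outside the grid.
#: It is a value, not an error; ligand-level scoring maps it to +inf.
OUT_OF_GRID = 127

REPULSIVE_RADIUS = 2.25  # A, solid sphere around backbone heavy atoms
ATTRACTIVE_MIN = 2.25  # A, inner edge of the attractive band
ATTRACTIVE_MAX = 4.75  # A, outer edge of the attractive band


def receptor_fingerprint(receptor: Receptor) -> str:
    """Hash of the receptor heavy-atom coordinates, for staleness checks."""
    data = np.ascontiguousarray(np.round(receptor.heavy_coords, 6))
    return hashlib.sha256(data.tobytes()).hexdigest()


@dataclass
class ScoringGrid:
    """Axis-aligned Cartesian tensor of cell values in {-1, 0, +1}."""

    origin: np.ndarray  # (3,), minimum corner, A
    spacing: float  # A per cell
    values: np.ndarray  # (nx, ny, nz) int8
    fingerprint: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("grid must be a non-empty 3-D tensor")
        bad = np.setdiff1d(np.unique(self.values), [-1, 0, 1])
        if bad.size:
            raise ValueError(f"grid cells must be -1/0/+1, found {bad}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def side_lengths(self) -> np.ndarray:
        return np.array(self.values.shape) * self.spacing

    def cell_index(self, coords: np.ndarray) -> np.ndarray:
        """Floor cell index of each coordinate row (may be out of bounds)."""
        return np.floor(
            (np.atleast_2d(coords) - self.origin) / self.spacing
        ).astype(np.int64)

    def cell_centers(self) -> np.ndarray:
        """Centers of all cells, shape (nx*ny*nz, 3), C order."""
        nx, ny, nz = self.values.shape
        ax = [self.origin[d] + (np.arange(n) + 0.5) * self.spacing
              for d, n in enumerate((nx, ny, nz))]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def save(self, path) -> None:
        header = {
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "dims": list(self.values.shape),
            "fingerprint": self.fingerprint,
        }
        np.savez_compressed(path, header=json.dumps(header), values=self.values)

    @classmethod
    def load(cls, path) -> "ScoringGrid":
        with np.load(path, allow_pickle=False) as npz:
            header = json.loads(str(npz["header"]))
            values = npz["values"]
        return cls(
            origin=np.array(header["origin"]),
            spacing=float(header["spacing"]),
            values=values,
            fingerprint=header.get("fingerprint", ""),
        )


def build_classic_grid(
    receptor: Receptor,
    center,
    side: float = 10.0,
    spacing: float = 0.25,
    *,
    ligand_extent: float = 0.0,
    translate_radius: float = 0.0,
) -> ScoringGrid:
    """Build the binary attractive/repulsive grid around ``center``.

    ``side`` defaults to 10 A (a 1000 A^3 cube) at 0.25 A spacing.  If
    ``ligand_extent``/``translate_radius`` are given and the configured cube
    could not keep every ligand atom in bounds after a maximal translation,
    the side is auto-expanded to ``ligand_extent + 2*translate_radius + 2``
    with a warning, so that moves are never artificially rejected.
    """
    if side <= 0 or spacing <= 0:
        raise ValueError("side and spacing must be positive")
    if spacing > side:
        raise ValueError("spacing larger than grid side")
    required = ligand_extent + 2.0 * translate_radius + 2.0
    if required > side:
        warnings.warn(
            f"grid side {side:.1f} A too small to guarantee in-bounds sampling; "
            f"auto-expanding to {required:.1f} A"
        )
        side = required

    center = np.asarray(center, dtype=float)
    n = max(1, int(np.ceil(side / spacing)))
    origin = center - 0.5 * n * spacing
    grid = ScoringGrid(
        origin=origin,
        spacing=spacing,
        values=np.zeros((n, n, n), dtype=np.int8),
        fingerprint=receptor_fingerprint(receptor),
    )

    centers = grid.cell_centers()
    heavy = receptor.heavy_coords
    if heavy.shape[0] == 0:
        raise ValueError("receptor has no heavy atoms")
    d_heavy, _ = cKDTree(heavy).query(centers, k=1)
    values = np.zeros(centers.shape[0], dtype=np.int8)
    attractive = (d_heavy >= ATTRACTIVE_MIN) & (d_heavy <= ATTRACTIVE_MAX)
    values[attractive] = -1
    backbone = receptor.backbone_heavy_coords
    if backbone.shape[0]:
        d_bb, _ = cKDTree(backbone).query(centers, k=1)
        values[d_bb < REPULSIVE_RADIUS] = 1  # repulsive wins over attractive
    grid.values = values.reshape(grid.values.shape)
    return grid


def score_point(grid: ScoringGrid, coord) -> int:
    """Value of the cell containing ``coord``; OUT_OF_GRID when outside.

    Boundary convention: floor((coord - origin)/spacing), so a point exactly
    on a cell boundary belongs to the higher-index cell.
    """
    idx = grid.cell_index(np.asarray(coord, dtype=float))[0]
    if np.any(idx < 0) or np.any(idx >= np.array(grid.values.shape)):
        return OUT_OF_GRID
    return int(grid.values[tuple(idx)])


def score_ligand(grid: ScoringGrid, heavy_coords: np.ndarray):
    """Grid score of a pose: sum of cell values over heavy atoms.

    Any heavy atom outside the grid makes the pose score +inf — the move is
    rejected rather than scored, because the grid cannot vouch for it.
    Returns ``(score, per_atom)`` where ``per_atom`` contains cell values
    with OUT_OF_GRID marking the offending atoms.
    """
    idx = grid.cell_index(heavy_coords)
    dims = np.array(grid.values.shape)
    in_bounds = np.all((idx >= 0) & (idx < dims), axis=1)
    per_atom = np.full(idx.shape[0], OUT_OF_GRID, dtype=np.int64)
    if in_bounds.any():
        ib = idx[in_bounds]
        per_atom[in_bounds] = grid.values[ib[:, 0], ib[:, 1], ib[:, 2]]
    if not in_bounds.all():
        return np.inf, per_atom
    return float(per_atom.sum()), per_atom


def check_rotate_acceptance(grid: ScoringGrid, heavy_coords: np.ndarray):
    """Orientation acceptance rule for the diverse-set Rotate step.

    Accept iff no heavy atom sits in a repulsive cell and at least 85% of
    heavy atoms sit in attractive cells.  Atoms outside the grid count as
    neither, which can only cause rejection.  Returns ``(ok, diagnostics)``.
    """
    _, per_atom = score_ligand(grid, heavy_coords)
    n = per_atom.shape[0]
    frac_attr = float((per_atom == -1).sum()) / n
    n_rep = int((per_atom == 1).sum())
    n_out = int((per_atom == OUT_OF_GRID).sum())
    ok = (n_rep == 0) and (n_out == 0) and (frac_attr >= 0.85)
    return ok, {
        "fraction_attractive": frac_attr,
        "fraction_repulsive": n_rep / n,
        "n_out_of_grid": n_out,
    }


@dataclass
class GridManager:
    """Owns named, weighted grids built against one receptor snapshot.

    The total ligand score is the weighted sum of per-grid scores.  The
    manager records the receptor fingerprint at build time and refuses to
    score against a receptor whose heavy atoms have moved since.
    """

    grids: list[tuple[str, ScoringGrid, float]] = field(default_factory=list)
    fingerprint: str = ""

    @classmethod
    def build(
        cls,
        receptor: Receptor,
        center,
        side: float = 10.0,
        spacing: float = 0.25,
        **kw,
    ) -> "GridManager":
        grid = build_classic_grid(receptor, center, side, spacing, **kw)
        return cls(grids=[("classic", grid, 1.0)], fingerprint=grid.fingerprint)

    @property
    def primary(self) -> ScoringGrid:
        return self.grids[0][1]

    def check_receptor(self, receptor: Receptor) -> None:
        if receptor_fingerprint(receptor) != self.fingerprint:
            raise ValueError(
                "receptor heavy atoms differ from those the grids were built "
                "against; rebuild the grids"
            )

    def score(self, heavy_coords: np.ndarray, receptor: Receptor | None = None) -> float:
        if receptor is not None:
            self.check_receptor(receptor)
        total = 0.0
        for _name, grid, weight in self.grids:
            s, _ = score_ligand(grid, heavy_coords)
            if np.isinf(s):
                return np.inf
            total += weight * s
        return total
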