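# gridock

Grid-scored low-resolution protein–ligand placement: binary
attractive/repulsive scoring grids, the legacy TransRot
(Translate/Rotate/Slide-Together) placement protocol, a Metropolis Monte
Carlo "Transform" placement sampler, simplified rigid-receptor refinement,
and a success-rate benchmarking harness driven by synthetic fixtures.

## What problem this addresses

The first stage of grid-based ligand docking must place a small molecule
in a non-clashing, plausibly bound position inside a receptor, cheaply
enough to generate hundreds of candidate models.  The classic approach
samples translation and rotation *independently*: translate the ligand's
center until a single probe atom clears the backbone, then search for an
acceptable orientation at that fixed position.  For non-globular ligands
this factorization is the weak point — a rod-shaped ligand enters a
rod-shaped pocket only if position and orientation are right
*simultaneously*, so independent stages waste most of their samples.

`gridock` implements both that legacy protocol and its replacement: a
Metropolis Monte Carlo walk over combined translation + rotation +
conformer-swap moves, scored on a precomputed grid, keeping the best pose
after a fixed cycle budget.  The package is aimed at people studying
docking sampling strategies who want a small, fully seeded, dependency-light
implementation whose every rule is unit-tested.

## The method in brief

**Scoring grid.**  A cubic tensor (default 10 Å side, 0.25 Å cells) over
the binding region.  Cell value +1 if within 2.25 Å of a backbone heavy
atom (clash), else −1 if 2.25–4.75 Å from any receptor heavy atom
(contact), else 0.  A pose scores Σ over heavy atoms of the cell values;
leaving the grid costs +∞.

**TransRot.**  Up to 50 random translations within 5 Å (accept the first
whose *neighbor atom* — the heavy atom nearest the ligand centroid — sits
in a cell ≤ 0); then up to 500 uniform reorientations accumulating a
diverse set (no repulsive atom, ≥85% attractive atoms, pairwise RMSD
> 0.65·√n_heavy; set size max(5, 5·rotatable bonds)) from which one member
is drawn; then 0.1 Å slides toward the receptor center of mass until just
before steric contact.

**Transform.**  500 Metropolis cycles at T = 1 on the grid score; each
cycle proposes a conformer swap (p = 0.1) or a rigid move (≤0.5 Å, ≤30°);
the neighbor atom is confined to a 5 Å box about the start; the
best-scoring accepted state wins.

**Refinement** (rigid receptor, surrogate pair score: soft quadratic
repulsion + triangular contact well): `MIN` = conformer re-selection + one
rigid-body minimization; `MCM` = six alternating perturb/minimize steps,
best of six, final minimization.

**Benchmark.**  Per complex, n seeded models; for each budget k, 20 random
subsamples; success = the subsample's lowest-scoring model lies within
2.0 Å heavy-atom RMSD (no superposition) of the native pose.

See `docs/methods.md` for conventions, parameter tables and limitations.

## Worked example

```python
import numpy as np
from gridock import (LigandSpec, make_synthetic_complex, PlacementConfig,
                     transform_place, ligand_rmsd)
from gridock.refine import FaScoreParams, refine_min

cx = make_synthetic_complex(
    "imprint", LigandSpec(n_atoms=8, shape="bent", n_rotatable=2), seed=11)
print("receptor atoms:", cx.receptor.n_atoms,
      "| ligand conformers:", cx.ligand.n_conformers)

grid = cx.grid_manager().primary
cfg = PlacementConfig(start_coord=cx.start_coord)
pose, traj = transform_place(cx.ligand, cx.receptor, grid, cfg,
                             np.random.default_rng(7))
print(f"grid score: {pose.grid_score:.1f} (best at cycle {traj.best_cycle})")

refined = refine_min(pose, cx.receptor, FaScoreParams())
rmsd = ligand_rmsd(refined.heavy_coords, cx.native_heavy_coords)
print(f"fa score after MIN refinement: {refined.fa_score:.2f}")
print(f"heavy-atom RMSD to native: {rmsd:.2f} A")
```

prints

```
receptor atoms: 126 | ligand conformers: 6
grid score: -8.0 (best at cycle 431)
fa score after MIN refinement: -27.85
heavy-atom RMSD to native: 0.92 A
```

The grid score of −8.0 means all 8 heavy atoms sit in attractive cells
(the imprint pocket's bore); refinement then settles the pose 0.92 Å from
the planted native — under the 2.0 Å success criterion.

A command-line interface mirrors the library:

```sh
gridock synth --pocket imprint --atoms 8 --rotbonds 2 --seed 11 --out-prefix cx
gridock make-grid --pdb cx_receptor.pdb --center 0,0,0 --out grid.npz
gridock place --algorithm transform --pdb cx_receptor.pdb --sdf cx_ligand.sdf \
              --start 1.0,0.5,0.0 --n-models 10 --seed 4 \
              --out poses.sdf --scores scores.tsv
gridock refine --method min --pdb cx_receptor.pdb --poses poses.sdf --out refined.sdf
gridock benchmark --protocol transform+min --pockets imprint --out curve.tsv
```

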