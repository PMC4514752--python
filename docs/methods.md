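# Methods

## Overview

`gridock` implements the low-resolution initial-placement stage of
grid-based protein–ligand docking, two placement algorithms that operate on
it, a simplified rigid-receptor refinement stage, and a synthetic
benchmarking harness.  Everything is Cartesian: a ligand pose is a list of
atom coordinates in the receptor frame, moved by rotation/translation
matrices.  There is no internal-coordinate machinery; for a system of one
small rigid body, direct coordinate transformation is both simpler and
faster.

## The binary scoring grid

The binding region is discretized into an axis-aligned cubic tensor
(default 10 Å side, 0.25 Å spacing — a 1000 Å³ cube) of integer cells:

* **+1 (repulsive)** — the cell center lies within 2.25 Å of any backbone
  heavy atom: placing a ligand atom here implies a backbone clash.
* **−1 (attractive)** — otherwise, the cell center lies 2.25–4.75 Å from
  any receptor heavy atom: favorable contact range.
* **0 (neutral)** — everything else.

Conventions chosen where the construction is underdetermined: repulsive
takes precedence over attractive where shells overlap (clash safety);
"shells with a radius of 2.25 Å" is read as the solid sphere; a cell's
value is defined by its center point; lookup is `floor((x − origin) /
spacing)` with no interpolation (values are categorical), so a point on a
cell boundary belongs to the higher-index cell.  A pose scores the sum of
cell values over its heavy atoms; any heavy atom outside the tensor makes
the pose score +∞, which implements "reject moves leaving the grid"
without a separate control path.

The grid side is a parameter because a fixed 10 Å cube cannot always
contain every ligand atom after a 5 Å translation: the builder auto-expands
to `ligand extent + 2·(translation radius) + 2 Å` with a warning when the
configured cube is too small.  A `GridManager` owns named, weighted grids
plus a hash of the receptor heavy-atom coordinates, and refuses to score
against a receptor that has moved since build time.  Only the classic
binary grid is implemented; the manager interface is the extension point
for additional terms.

## TransRot: independent translate / rotate / slide

1. **Translate** — up to 50 uniform random offsets within 5.0 Å of the
   starting position; the first proposal whose *neighbor atom* (the heavy
   atom closest to the heavy-atom centroid) lands in an attractive or
   neutral cell is accepted.  Exhaustion returns the last proposal with a
   failure flag rather than raising, so batch model generation continues.
2. **Rotate** — up to 500 uniform SO(3) reorientations about the
   heavy-atom centroid accumulate a diverse set: a candidate joins if no
   heavy atom is repulsive, ≥85% of heavy atoms are attractive, and its
   RMSD to every member already accepted exceeds 0.65·√(n_heavy) Å.  The
   target set size is max(5, 5·rotatable bonds).  One member is returned
   uniformly at random; an empty set flags failure and leaves the pose.
3. **Slide Together** — 0.1 Å translations toward the receptor center of
   mass (declared convention: the unweighted heavy-atom centroid) while
   the hard-sphere clash count stays zero, guaranteeing contact before
   refinement.

The entry pose is the ligand's first conformer, reoriented once uniformly
at random: the conformer's internal frame carries no information about the
receptor frame, and without this both algorithms would inherit whatever
orientation the input file happened to use.

## Transform: Metropolis Monte Carlo on the grid

The ligand starts at the user-supplied coordinate in a uniformly random
orientation (conformer 0) and takes 500 cycles.  Each cycle proposes either
a conformer swap (probability 0.1 when a library is present; the new
conformer keeps the accumulated rotation and the current heavy-atom
centroid) or a combined rigid move: translation uniform in a 0.5 Å ball
plus rotation about a random axis by up to 30°.  Proposals are scored on
the grid; a proposal placing the neighbor atom beyond the sampling-box
radius (default: the 5 Å translation radius) of the start, or any heavy
atom outside the tensor, scores +∞.  The Metropolis criterion
(T = 1 on the grid-score scale) accepts or rejects; after all cycles the
best-scoring accepted state is returned.

Two choices deserve note.  Per-cycle move magnitudes and the swap
probability are not prescribed by the method definition; the defaults were
chosen once so that a 500-cycle walk can traverse the 5 Å box, and are all
exposed in `PlacementConfig`.  Second, because the grid is piecewise
constant the optimum is typically a *plateau* of tied scores; the best-pose
tracker updates on ties, so the returned pose is the most recent tied
state.  With a strict-improvement tracker the returned pose would always be
the first plateau cell entered — systematically the shallowest point of the
pocket — whereas tie-updating lets the walk diffuse over the plateau and
returns an unbiased sample of it.

`metropolis_accept` is exact: downhill always accepted, uphill with
probability exp(−Δ/T), +∞ never; a calibration test pins the acceptance
frequency at Δ = +1, T = 1 to e⁻¹ within Monte Carlo error.

## Surrogate full-atom score and refinement

The refinement stage of the original pipeline optimizes an all-atom energy
with side-chain repacking.  Here the receptor is rigid and scoring uses a
deliberately simple continuous pair potential over ligand/receptor
heavy-atom pairs:

    E = Σ [ w_rep · max(0, (rᵢ + rⱼ − τ) − d)²
            − w_atr · max(0, 1 − |d − (rᵢ + rⱼ)| / w) ]

with clash tolerance τ = 0.6 Å, well width w = 1.5 Å, w_rep = 1,
w_atr = 0.25, and Bondi-style van der Waals radii from a built-in element
table.  The form was chosen for continuity, zero score at separation and
cheap evaluation; it is a stand-in for chemistry-aware scoring, not an
approximation of any specific force field.  A "clash" for the hard count
used by Slide Together is a pair closer than rᵢ + rⱼ − τ.

* **MIN** — re-select the library conformer scoring best at the current
  placement (each conformer positioned by least-squares superposition onto
  the current pose, so placement changes as little as the new internal
  geometry allows), then one rigid-body 6-DOF local minimization.
* **MCM** — six steps alternating conformer-reselection + minimization
  (odd) with small random perturbations of 0.1 Å / 20° (even); the pose
  recorded after each step competes, the best of the six gets a final
  minimization.  The schedule compares the poses as recorded, not only
  post-minimization scores.

The minimizer is a derivative-free pattern search over the 6 rigid DOF
(translation steps from 0.25 Å, rotation steps from 0.1 rad, halved on
failure to improve, terminating below 0.01).  Its contract is descent and
convergence, not a particular optimizer; the constructed-well test checks
it returns to a known minimum within 0.05 Å.  Conformer re-selection by
superposition replaces the original pipeline's side-chain repacking cycle;
with a rigid receptor, ligand conformer choice is the only discrete degree
of freedom left.

## Synthetic fixtures

Real benchmark complexes cannot ship inside a test suite, so fixtures are
generated: all-carbon pseudo-ligands (rod, bent or globular topology, 3–30
atoms, 0–3 rotatable bonds — rotatable-bond count is controlled through
bond orders so the detection rule finds exactly the requested number) and
pseudo-receptors whose backbone-flagged walls line a pocket around the
ligand's native pose:

* **rod_channel / bent_channel** — rings of wall atoms (radius 4.2 Å)
  around the smoothed chain axis, closed by a cap at one end, ending at
  the ligand's far end with a doubled, azimuthally staggered rim.  Every
  wall carries a second "jacket" layer 2.2 Å further out, standing in for
  the protein body behind a binding-site surface: without it the exterior
  face of a one-atom-thick wall is just as attractive as the pocket
  interior, which no real pocket exhibits.
* **imprint** — a shell of wall atoms at 3.5 Å from every ligand atom
  (jacketed likewise) with a 50° opening cone: a deep, shape-specific
  pocket.  Bent ligands bend at n/3 rather than the midpoint: with equal
  arms the flipped ligand nearly fits its own imprint, and the recovery
  experiment would be testing a fixture artifact instead of the sampler.
* **open_shelf** — a flat double-layered plate 3.5 Å below the ligand: a
  shallow surface site with weak orientation preference.

Wall atoms keep ≥3.0 Å from every native ligand atom (hard filter), so
native poses are clash-free by construction; imprint natives are verified
to satisfy the 85%-attractive orientation rule on the default grid.  The
starting coordinate emulates a user-supplied approximate binding-site
center: the native centroid displaced 2.5 Å in a seed-determined random
direction — it may fall inside the pocket, against a wall, or just outside
the mouth, exactly as a hand-picked site center would.

What these fixtures do *not* emulate: real atom-type diversity, hydrogen
bonding or electrostatics, receptor flexibility, solvent, and ligands
larger than ~30 atoms.  Passing tests therefore demonstrate the sampling
and scoring machinery behaves as specified, not that the surrogate score
would rank real chemotypes correctly.

## Conformer enumeration

Torsion settings are enumerated at 120° steps per rotatable bond by rigid
rotation of one bond side (bond lengths exactly preserved), settings with
an atom pair at graph distance ≥3 closer than 0.7·(rᵢ + rⱼ) are dropped,
and the rest is uniformly subsampled to the cap (default 100; synthetic
fixtures use 27).  Bonded 1-2 and 1-3 pairs are excluded from the clash
test — their distances are fixed by the skeleton and always below that
cutoff, so including them would reject every conformer.

## Benchmarking

For a protocol (placement × refinement) and a set of complexes, a pool of
independently seeded models is generated per complex (seeds spawned from
one master `SeedSequence`, so the entire benchmark is reproducible to the
byte).  For each model budget k, 20 random subsamples of size k are drawn;
each subsample contributes its lowest-full-atom-score model, a success
when that model is within 2.0 Å heavy-atom RMSD of the native pose.  RMSD
is computed over heavy atoms with the identity atom mapping, no
superposition and no symmetry correction — the fixed receptor frame is the
point — and the success curve reports mean ± sd over resamples of the
fraction of complexes docked.  Budgets default to {10, 25, 50, 100, 150};
model counts rather than wall-clock time index the curves, since timing is
hardware-bound.

The placement-only comparison (`compare_placements`) runs both algorithms
with identical per-run seed streams and reports the fraction of final
poses under threshold plus the per-state enrichment (fraction of all
visited states under threshold; per accepted Monte Carlo state for
Transform, per stage snapshot for TransRot).  Refinement is deliberately
excluded there to isolate the sampling question.

## Problem sizes in the shipped experiments

The acceptance experiments use 10 rod-channel complexes × 100 paired runs
per algorithm for the placement comparison, and 2 imprint fixtures × 10
replicates × 150 transform+MIN models for native recovery.  These sizes
give two-digit success-percentage stability across master seeds while
keeping a full run in a few CPU-minutes; they are the package's default
study conditions, not tuned quantities.

## Known limitations

* RMSD is not symmetry-corrected; near-symmetric ligands (e.g. perfect
  rods flipped end-to-end) are scored as failures even when the placement
  is geometrically equivalent.  Rod-channel success fractions are
  correspondingly conservative for both algorithms.
* The binary grid cannot distinguish poses within an all-attractive
  plateau; final placement accuracy beyond ~1 Å comes from refinement,
  not from the grid.
* The surrogate score has no notion of chemistry; Kd-style affinity
  prediction is out of scope.
* Hydrogens are ignored throughout (ligand inputs are expected
  heavy-atom only, receptors drop H on read), so the 85% rule counts
  heavy atoms.
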