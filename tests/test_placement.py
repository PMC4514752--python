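"""TransRot stages, Metropolis criterion and the Transform sampler."""

import math

import numpy as np
import pytest

from gridock.grid import ScoringGrid, score_ligand, score_point
from gridock.model import Pose, ligand_rmsd
from gridock.placement import (
    PlacementConfig,
    metropolis_accept,
    rotate_step,
    slide_together,
    transform_place,
    translate_step,
    transrot_place,
)
from gridock.refine import FaScoreParams, count_clashes


def uniform_grid(value, n=40, spacing=0.5, origin=-10.0):
    values = np.full((n, n, n), value, dtype=np.int8)
    return ScoringGrid(origin=np.full(3, origin), spacing=spacing,
                       values=values)


def make_pose(mol, at=None):
    coords = mol.conformers[0].copy()
    if at is not None:
        coords = coords - coords[mol.heavy_mask].mean(axis=0) + np.asarray(at)
    return Pose(molecule=mol, conformer_index=0, coords=coords)


class TestTranslateStep:
    def test_attractive_grid_accepts_first_attempt(self, random_molecule):
        mol = random_molecule()
        cfg = PlacementConfig(start_coord=np.zeros(3))
        pose = translate_step(make_pose(mol, np.zeros(3)),
                              uniform_grid(-1), cfg, np.random.default_rng(0))
        assert pose.provenance["translate_attempts"] == 1
        assert not pose.provenance["translate_failed"]

    def test_all_repulsive_grid_exhausts_attempts(self, random_molecule):
        mol = random_molecule()
        cfg = PlacementConfig(start_coord=np.zeros(3))
        pose = translate_step(make_pose(mol, np.zeros(3)),
                              uniform_grid(1), cfg, np.random.default_rng(0))
        assert pose.provenance["translate_attempts"] == 50
        assert pose.provenance["translate_failed"]

    def test_zero_radius_leaves_pose_in_place(self, random_molecule):
        mol = random_molecule()
        cfg = PlacementConfig(start_coord=np.zeros(3), translate_radius=0.0)
        start = make_pose(mol, np.zeros(3))
        pose = translate_step(start, uniform_grid(0), cfg,
                              np.random.default_rng(0))
        np.testing.assert_allclose(pose.coords, start.coords)
        assert not pose.provenance["translate_failed"]


class TestRotateStep:
    def test_diverse_set_size_formula(self):
        cfg = PlacementConfig(start_coord=np.zeros(3))
        assert cfg.diverse_set_size(0) == 5
        assert cfg.diverse_set_size(1) == 5
        assert cfg.diverse_set_size(2) == 10
        assert cfg.diverse_set_size(3) == 15

    def test_rmsd_threshold_formula(self):
        cfg = PlacementConfig(start_coord=np.zeros(3))
        assert cfg.rmsd_diversity_threshold(16) == pytest.approx(2.6)

    def test_all_neutral_grid_builds_empty_set(self, random_molecule):
        """0% attractive can never meet the 85% rule."""
        mol = random_molecule()
        cfg = PlacementConfig(start_coord=np.zeros(3))
        start = make_pose(mol, np.zeros(3))
        pose = rotate_step(start, uniform_grid(0), cfg,
                           np.random.default_rng(0))
        assert pose.provenance["rotate_failed"]
        np.testing.assert_allclose(pose.coords, start.coords)

    def test_accepted_members_satisfy_rules_on_fixture(self, rod_complex):
        """Returned orientation honors clash, 85% and diversity bounds."""
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        mol = cx.ligand
        # place at the native centroid, where good orientations exist
        pose = make_pose(mol, cx.native_heavy_coords.mean(axis=0))
        found = 0
        for seed in range(8):
            out = rotate_step(pose, grid, cfg, np.random.default_rng(seed))
            if out.provenance["rotate_failed"]:
                continue
            found += 1
            from gridock.grid import check_rotate_acceptance

            ok, diag = check_rotate_acceptance(grid, out.heavy_coords)
            assert ok, diag
            assert out.provenance["rotate_set_size"] <= cfg.diverse_set_size(
                mol.n_rotatable_bonds)
        assert found > 0


class TestSlideTogether:
    def test_clashing_entry_returns_flagged(self, rod_complex):
        cx = rod_complex
        # drop the ligand straight into the wall
        wall_point = cx.receptor.heavy_coords[0]
        pose = make_pose(cx.ligand, wall_point)
        out = slide_together(pose, cx.receptor, FaScoreParams())
        assert out.provenance["slide_entry_clash"]
        np.testing.assert_allclose(out.coords, pose.coords)

    def test_stops_one_step_before_contact(self):
        """Post-slide pose is clash-free; one further step clashes (1-D
        line-search oracle against a flat wall)."""
        from gridock.model import Molecule, Pose, Receptor

        ys, zs = np.meshgrid(np.arange(-4.5, 4.6, 1.5),
                             np.arange(-4.5, 4.6, 1.5))
        wall = np.column_stack([np.zeros(ys.size), ys.ravel(), zs.ravel()])
        rec = Receptor(elements=["C"] * len(wall), coords=wall,
                       backbone_mask=np.zeros(len(wall), dtype=bool))
        mol = Molecule(elements=["C"],
                       conformers=[np.array([[6.0, 0.0, 0.0]])])
        pose = Pose(molecule=mol, conformer_index=0,
                    coords=np.array([[6.0, 0.0, 0.0]]))
        params = FaScoreParams()
        step = 0.1
        out = slide_together(pose, rec, params, step=step)
        final = out.coords
        radii = np.array([1.7])
        assert count_clashes(final, radii, rec, params) == 0
        # contact at x = 3.4 - 0.6 = 2.8: the slide must stop just above it
        assert 2.8 <= final[0, 0] <= 2.8 + 2 * step
        nxt = final + step * (rec.center_of_mass - final[0]) / np.linalg.norm(
            rec.center_of_mass - final[0])
        assert count_clashes(nxt, radii, rec, params) > 0

    def test_free_path_reaches_center_of_mass(self):
        """With no obstacle en route the centroid ends within one step of
        the receptor center of mass."""
        from gridock.model import Molecule, Pose, Receptor

        # two distant side-chain atoms; COM between them, far from both
        rec = Receptor(elements=["C", "C"],
                       coords=np.array([[0.0, 30.0, 0.0], [0.0, -30.0, 0.0]]),
                       backbone_mask=np.zeros(2, dtype=bool))
        mol = Molecule(elements=["C"],
                       conformers=[np.array([[8.0, 0.0, 0.0]])])
        pose = Pose(molecule=mol, conformer_index=0,
                    coords=np.array([[8.0, 0.0, 0.0]]))
        out = slide_together(pose, rec, FaScoreParams(), step=0.1)
        assert np.linalg.norm(out.coords[0] - rec.center_of_mass) <= 0.1 + 1e-9


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert metropolis_accept(-1.0, 1.0, rng)
        assert metropolis_accept(0.0, 1.0, rng)

    def test_infinite_uphill_never_accepted(self):
        rng = np.random.default_rng(0)
        assert not metropolis_accept(np.inf, 1.0, rng)

    def test_acceptance_frequency_matches_boltzmann(self):
        """P(accept | delta=+1, T=1) = e^-1 within Monte Carlo error."""
        rng = np.random.default_rng(123)
        n = 100_000
        hits = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n))
        assert hits / n == pytest.approx(math.exp(-1.0), abs=0.01)

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, np.random.default_rng(0))


class TestTransformPlace:
    def test_best_pose_is_best_accepted_state(self, rod_complex):
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        pose, traj = transform_place(cx.ligand, cx.receptor, grid, cfg,
                                     np.random.default_rng(0))
        finite = [s for s in traj.current_scores if np.isfinite(s)]
        assert pose.grid_score == min(finite)
        assert traj.n_cycles == cfg.transform_cycles

    def test_no_returned_atom_out_of_grid_or_box(self, rod_complex):
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        nbr = cx.ligand.neighbor_atom
        for seed in range(5):
            pose, _ = transform_place(cx.ligand, cx.receptor, grid, cfg,
                                      np.random.default_rng(seed))
            score, per_atom = score_ligand(grid, pose.heavy_coords)
            assert np.isfinite(score)
            assert np.linalg.norm(
                pose.coords[nbr] - cfg.start_coord) <= cfg.box_radius + 1e-9

    def test_greedy_limit_scores_non_increasing(self, rod_complex):
        """As T -> 0 Metropolis becomes greedy descent."""
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord,
                              mc_temperature=1e-9)
        _, traj = transform_place(cx.ligand, cx.receptor, grid, cfg,
                                  np.random.default_rng(1))
        scores = [s for s in traj.current_scores if np.isfinite(s)]
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_same_seed_bit_identical(self, rod_complex):
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        p1, t1 = transform_place(cx.ligand, cx.receptor, grid, cfg,
                                 np.random.default_rng(5))
        p2, t2 = transform_place(cx.ligand, cx.receptor, grid, cfg,
                                 np.random.default_rng(5))
        np.testing.assert_array_equal(p1.coords, p2.coords)
        assert t1.current_scores == t2.current_scores
        assert t1.accepted == t2.accepted

    def test_internal_geometry_preserved_or_conformer_matched(
            self, imprint_complex):
        """Every returned pose is a rigid image of a library conformer."""
        cx = imprint_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        for seed in range(3):
            pose, _ = transform_place(cx.ligand, cx.receptor, grid, cfg,
                                      np.random.default_rng(seed))
            conf = cx.ligand.conformers[pose.conformer_index]
            heavy = cx.ligand.heavy_mask
            d_pose = np.linalg.norm(
                pose.coords[heavy][:, None] - pose.coords[heavy][None, :],
                axis=2)
            d_conf = np.linalg.norm(
                conf[heavy][:, None] - conf[heavy][None, :], axis=2)
            np.testing.assert_allclose(d_pose, d_conf, atol=1e-6)

    def test_conformer_swaps_proposed_when_library_present(
            self, imprint_complex):
        cx = imprint_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        _, traj = transform_place(cx.ligand, cx.receptor, grid, cfg,
                                  np.random.default_rng(0))
        assert traj.acceptance_counts["conformer_swap"]["proposed"] > 0


class TestTransrotPlace:
    def test_same_seed_bit_identical(self, rod_complex):
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        p1, _ = transrot_place(cx.ligand, cx.receptor, grid, cfg,
                               np.random.default_rng(2))
        p2, _ = transrot_place(cx.ligand, cx.receptor, grid, cfg,
                               np.random.default_rng(2))
        np.testing.assert_array_equal(p1.coords, p2.coords)

    def test_narrow_channel_produces_rotate_failures(self, rod_complex):
        """The rod-in-channel failure mode: the independent Rotate stage
        often cannot find any acceptable orientation."""
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        failures = 0
        for seed in range(30):
            pose, _ = transrot_place(cx.ligand, cx.receptor, grid, cfg,
                                     np.random.default_rng(seed))
            failures += pose.provenance["rotate_failed"]
        assert failures > 0

    def test_stage_snapshots_returned(self, rod_complex):
        cx = rod_complex
        grid = cx.grid_manager().primary
        cfg = PlacementConfig(start_coord=cx.start_coord)
        _, states = transrot_place(cx.ligand, cx.receptor, grid, cfg,
                                   np.random.default_rng(0))
        assert len(states) == 3  # translate, rotate, slide
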