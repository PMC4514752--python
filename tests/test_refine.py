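"""Surrogate full-atom score and the MIN / MCM refinement schedules."""

import numpy as np
import pytest

from gridock.model import Molecule, Pose, Receptor
from gridock.refine import (
    FaScoreParams,
    RefinementConfig,
    count_clashes,
    fa_score,
    pose_fa_score,
    refine_mcm,
    refine_min,
    rigid_minimize,
)


def single_atom_receptor(at=(0.0, 0.0, 0.0), element="C"):
    return Receptor(elements=[element], coords=np.array([at], dtype=float),
                    backbone_mask=np.array([False]))


def carbon_pose(coords, conformers=None):
    coords = np.asarray(coords, dtype=float)
    mol = Molecule(elements=["C"] * len(coords),
                   conformers=conformers or [coords])
    return Pose(molecule=mol, conformer_index=0, coords=coords)


class TestCountClashes:
    def test_distant_ligand_has_no_clashes(self, random_receptor):
        rec = random_receptor(n_atoms=20, seed=0)
        lig = np.full((4, 3), 50.0)
        assert count_clashes(lig, np.full(4, 1.7), rec, FaScoreParams()) == 0

    def test_single_carbon_pair_inside_cutoff(self):
        # contact 3.4, tolerance 0.6 -> clash below 2.8
        rec = single_atom_receptor()
        lig = np.array([[2.0, 0.0, 0.0]])
        assert count_clashes(lig, np.array([1.7]), rec, FaScoreParams()) == 1
        lig = np.array([[2.9, 0.0, 0.0]])
        assert count_clashes(lig, np.array([1.7]), rec, FaScoreParams()) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_all_pairs_oracle(self, random_receptor, seed):
        rng = np.random.default_rng(seed)
        rec = random_receptor(n_atoms=40, seed=seed)
        lig = rng.uniform(-5, 5, size=(6, 3))
        radii = np.full(6, 1.7)
        params = FaScoreParams()
        # independent O(N*M) enumeration
        expected = 0
        for i in range(6):
            for j in range(rec.n_atoms):
                d = np.linalg.norm(lig[i] - rec.coords[j])
                rj = rec.heavy_vdw_radii[j]
                expected += d < radii[i] + rj - params.clash_tolerance
        assert count_clashes(lig, radii, rec, params) == expected


class TestFaScore:
    def test_isolated_ligand_scores_zero(self, random_receptor):
        rec = random_receptor(n_atoms=10, seed=0)
        lig = np.full((3, 3), 100.0)
        assert fa_score(lig, np.full(3, 1.7), rec, FaScoreParams()) == 0.0

    def test_pair_at_contact_distance_scores_minus_w_atr(self):
        rec = single_atom_receptor()
        params = FaScoreParams()
        lig = np.array([[3.4, 0.0, 0.0]])  # exactly r_i + r_j
        s = fa_score(lig, np.array([1.7]), rec, params)
        assert s == pytest.approx(-params.w_atr)

    def test_continuity_under_small_displacement(self, random_receptor):
        rec = random_receptor(n_atoms=20, seed=1)
        rng = np.random.default_rng(0)
        lig = rng.uniform(-4, 4, size=(5, 3))
        radii = np.full(5, 1.7)
        params = FaScoreParams()
        s0 = fa_score(lig, radii, rec, params)
        for eps in (1e-3, 1e-5):
            s = fa_score(lig + eps, radii, rec, params)
            assert abs(s - s0) < 100 * eps * 5

    def test_finite_difference_matches_directional_derivative(self):
        """Central differences agree at two scales away from the kinks."""
        rec = single_atom_receptor()
        params = FaScoreParams()
        radii = np.array([1.7])
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = np.array([[2.0 + rng.random() * 2.5, 0.3, -0.2]])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            h1, h2 = 1e-4, 1e-5
            d1 = (fa_score(x + h1 * direction, radii, rec, params)
                  - fa_score(x - h1 * direction, radii, rec, params)) / (2 * h1)
            d2 = (fa_score(x + h2 * direction, radii, rec, params)
                  - fa_score(x - h2 * direction, radii, rec, params)) / (2 * h2)
            assert d1 == pytest.approx(d2, abs=1e-4 + 1e-3 * abs(d2))


class TestRigidMinimize:
    def test_descent_contract(self, rod_complex):
        cx = rod_complex
        params = FaScoreParams()
        pose = Pose(molecule=cx.ligand, conformer_index=0,
                    coords=cx.native_pose.coords + np.array([0.5, 0.2, 0.0]))
        before = pose_fa_score(pose, cx.receptor, params)
        out = rigid_minimize(pose, cx.receptor, params)
        assert out.fa_score <= before + 1e-12

    def test_recovers_constructed_well_minimum(self):
        """Octahedral cage of attractors with a known center: a displaced
        single-atom ligand must return to the middle."""
        r = 3.4  # contact distance for C-C
        sites = r * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                              [0, -1, 0], [0, 0, 1], [0, 0, -1.0]])
        rec = Receptor(elements=["C"] * 6, coords=sites,
                       backbone_mask=np.zeros(6, dtype=bool))
        pose = carbon_pose(np.array([[0.3, 0.0, 0.0]]))
        out = rigid_minimize(pose, rec, FaScoreParams())
        assert np.linalg.norm(out.coords[0]) < 0.05

    def test_already_minimal_pose_stays_put(self):
        r = 3.4
        sites = r * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                              [0, -1, 0], [0, 0, 1], [0, 0, -1.0]])
        rec = Receptor(elements=["C"] * 6, coords=sites,
                       backbone_mask=np.zeros(6, dtype=bool))
        pose = carbon_pose(np.zeros((1, 3)))
        out = rigid_minimize(pose, rec, FaScoreParams())
        assert np.linalg.norm(out.coords[0]) < 0.05


class TestRefineSchedules:
    def test_min_single_conformer_equals_rigid_minimize(self, rod_complex):
        cx = rod_complex
        params = FaScoreParams()
        pose = Pose(molecule=cx.ligand, conformer_index=0,
                    coords=cx.native_pose.coords + 0.3)
        a = refine_min(pose, cx.receptor, params)
        b = rigid_minimize(pose, cx.receptor, params)
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-12)

    def test_blocked_conformer_not_selected(self):
        """Of two conformers, the sterically blocked one must lose."""
        # receptor: a wall of atoms in the y-z plane at x = 0
        ys, zs = np.meshgrid(np.arange(-3, 4, 1.5), np.arange(-3, 4, 1.5))
        wall = np.column_stack(
            [np.zeros(ys.size), ys.ravel(), zs.ravel()])
        rec = Receptor(elements=["C"] * len(wall), coords=wall,
                       backbone_mask=np.zeros(len(wall), dtype=bool))
        # conformer 0: compact pair along x (clear of the wall);
        # conformer 1: stretched along x so one atom pierces the wall
        c_free = np.array([[3.6, 0.2, 0.2], [5.1, 0.2, 0.2]])
        c_blocked = np.array([[3.6, 0.2, 0.2], [0.0, 0.2, 0.2]])
        mol = Molecule(elements=["C", "C"],
                       conformers=[c_blocked, c_free],
                       bonds=[(0, 1, 1)])
        pose = Pose(molecule=mol, conformer_index=0, coords=c_blocked)
        out = refine_min(pose, rec, FaScoreParams(),
                         RefinementConfig(min_max_iter=5))
        assert out.conformer_index == 1

    def test_mcm_score_never_worse_than_entry(self, imprint_complex):
        cx = imprint_complex
        params = FaScoreParams()
        pose = Pose(molecule=cx.ligand, conformer_index=0,
                    coords=cx.native_pose.coords + np.array([1.0, 0.4, 0.2]))
        entry = pose_fa_score(pose, cx.receptor, params)
        out = refine_mcm(pose, cx.receptor, params,
                         rng=np.random.default_rng(0))
        assert out.fa_score <= entry + 1e-9

    def test_mcm_deterministic_given_seed(self, imprint_complex):
        cx = imprint_complex
        params = FaScoreParams()
        pose = Pose(molecule=cx.ligand, conformer_index=0,
                    coords=cx.native_pose.coords + 0.5)
        a = refine_mcm(pose, cx.receptor, params,
                       rng=np.random.default_rng(9))
        b = refine_mcm(pose, cx.receptor, params,
                       rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_min_output_score_never_worse_than_entry(self, imprint_complex):
        cx = imprint_complex
        params = FaScoreParams()
        pose = Pose(molecule=cx.ligand, conformer_index=0,
                    coords=cx.native_pose.coords + np.array([0.8, 0.1, 0.3]))
        entry = pose_fa_score(pose, cx.receptor, params)
        out = refine_min(pose, cx.receptor, params)
        assert out.fa_score <= entry + 1e-9
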