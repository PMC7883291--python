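"""Restraints, the interaction-space scan, docking, model selection."""

import numpy as np
import pytest

from igxlink import (
    Body,
    DistanceRestraint,
    DomainDefinition,
    RigidPose,
    accessible_interaction_scan,
    build_restraints,
    count_clashes,
    quasi_uniform_rotations,
    restraint_energy,
    rigid_dock,
    select_model,
)
from igxlink.rigidmodel import (
    DockingError,
    RestraintError,
    ScanError,
    rotation_grid_starts,
)
from igxlink.synthetic import planted_docking_problem


@pytest.fixture(scope="module")
def planted():
    return planted_docking_problem(4)


class TestDomainsAndRestraints:
    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            DomainDefinition("d", [(1, 10), (5, 20)])

    def test_eight_interbody_links_give_eight_restraints(self):
        fixed_dom = DomainDefinition("fixed", [(1, 100)])
        mobile_dom = DomainDefinition("mobile", [(101, 200)])
        keys = {("P", i, "P", 100 + i) for i in range(1, 9)}
        restraints, excluded = build_restraints(keys, fixed_dom, mobile_dom)
        assert len(restraints) == 8 and excluded == []
        assert all(r.target_mean == 17.0 and r.sd == 2.0 for r in restraints)
        assert all(r.lower_bound == 3.0 and r.upper_bound == 30.0
                   for r in restraints)

    def test_intra_body_links_excluded_and_counted(self):
        fixed_dom = DomainDefinition("fixed", [(1, 100)])
        mobile_dom = DomainDefinition("mobile", [(101, 200)])
        keys = {("P", 5, "P", 150), ("P", 5, "P", 50)}
        restraints, excluded = build_restraints(keys, fixed_dom, mobile_dom)
        assert len(restraints) == 1 and len(excluded) == 1

    def test_zero_interbody_links_raise(self):
        with pytest.raises(RestraintError):
            build_restraints({("P", 1, "P", 2)},
                             DomainDefinition("f", [(1, 10)]),
                             DomainDefinition("m", [(100, 110)]))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DistanceRestraint(1, 2, target_mean=40.0)  # mean above upper


class TestRestraintEnergy:
    def test_zero_inside_flat_bottom(self, planted):
        fixed, mobile, restraints = planted
        e, d = restraint_energy(RigidPose.identity(), restraints, fixed, mobile)
        assert e == 0.0

    def test_closed_form_single_violation(self):
        fixed = Body([1], [[0.0, 0, 0]])
        mobile = Body([2], [[21.0, 0, 0]])
        r = DistanceRestraint(1, 2, target_mean=17.0, sd=2.0)
        e, d = restraint_energy(RigidPose.identity(), [r], fixed, mobile)
        assert d[0] == 21.0
        assert abs(e - 1.0) < 1e-12  # ((21-17-2)/2)^2

    def test_vectorized_matches_per_term_summation(self, planted):
        fixed, mobile, restraints = planted
        pose = RigidPose(rotation=np.eye(3), translation=np.array([4.0, 1.0, -2.0]))
        e, dists = restraint_energy(pose, restraints, fixed, mobile)
        manual = 0.0
        for r, d in zip(restraints, dists):
            v = max(0.0, abs(d - r.target_mean) - r.sd) / r.sd
            manual += v * v
        assert abs(e - manual) < 1e-10

    def test_invariant_under_joint_rigid_transform(self, planted):
        fixed, mobile, restraints = planted
        pose = RigidPose(rotation=np.eye(3), translation=np.array([2.0, 0, 0]))
        e1, _ = restraint_energy(pose, restraints, fixed, mobile)
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        shift = np.array([5.0, -9.0, 2.0])
        fixed2 = Body(fixed.resnums, fixed.coords @ R.T + shift)
        mobile2 = Body(mobile.resnums, mobile.coords @ R.T + shift)
        # same relative pose expressed in the rotated frame
        pose2 = RigidPose(rotation=R @ pose.rotation @ R.T,
                          translation=R @ pose.translation)
        e2, _ = restraint_energy(pose2, restraints, fixed2, mobile2)
        assert abs(e1 - e2) < 1e-9

    def test_missing_restraint_residue_raises(self, planted):
        fixed, mobile, _ = planted
        bad = [DistanceRestraint(99999, int(mobile.resnums[0]))]
        with pytest.raises(RestraintError):
            restraint_energy(RigidPose.identity(), bad, fixed, mobile)


class TestRotationSampling:
    def test_rotations_are_proper_orthonormal(self):
        for R in quasi_uniform_rotations(64):
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) > 0

    def test_deterministic(self):
        np.testing.assert_array_equal(quasi_uniform_rotations(32),
                                      quasi_uniform_rotations(32))


class TestInteractionScan:
    @pytest.fixture(scope="class")
    def scan(self, planted):
        fixed, mobile, restraints = planted
        return accessible_interaction_scan(
            fixed, mobile, restraints, n_orientations=96, grid_spacing=4.0)

    def test_nk_non_increasing(self, scan):
        nk = scan.n_consistent
        assert all(nk[k] >= nk[k + 1] for k in range(len(nk) - 1))

    def test_exact_counts_sum_to_clash_free_total(self, scan):
        assert scan.n_by_exact_k.sum() == scan.n_clash_free
        assert scan.n_consistent[0] == scan.n_clash_free

    def test_planted_pose_recovered_within_one_grid_step(self, planted):
        fixed, mobile, restraints = planted
        scan = accessible_interaction_scan(
            fixed, mobile, restraints, n_orientations=192, grid_spacing=3.0)
        full = [p for p in scan.best_poses
                if p.n_satisfied == len(restraints)]
        assert full, "no scanned pose satisfies every restraint"
        best_err = min(float(np.linalg.norm(p.translation)) for p in full)
        assert best_err <= 3.0 + 1e-9  # one translation grid step

    def test_no_restraints_raise(self, planted):
        fixed, mobile, _ = planted
        with pytest.raises(ScanError):
            accessible_interaction_scan(fixed, mobile, [])


class TestRigidDock:
    def test_start_at_truth_returns_zero_energy_rank_one(self, planted):
        fixed, mobile, restraints = planted
        dock = rigid_dock(fixed, mobile, restraints, [RigidPose.identity()])
        p = dock.poses[0]
        assert p.restraint_energy == 0.0
        assert float(np.linalg.norm(p.translation)) < 2.0

    def test_identical_starts_collapse_to_one_cluster(self, planted):
        fixed, mobile, restraints = planted
        starts = [RigidPose.identity(), RigidPose.identity()]
        dock = rigid_dock(fixed, mobile, restraints, starts,
                          early_stop_energy=None)
        assert len(dock.clusters) == 1 and len(dock.clusters[0]) == 2

    def test_refinement_never_worsens_restraint_energy(self, planted):
        fixed, mobile, restraints = planted
        starts = rotation_grid_starts(fixed, mobile, restraints,
                                      n_orientations=48, n_starts=6)
        dock = rigid_dock(fixed, mobile, restraints, starts,
                          early_stop_energy=None)
        energies = [p.restraint_energy for p in dock.poses]
        starts_e = sorted(restraint_energy(s, restraints, fixed, mobile)[0]
                          for s in starts)
        assert min(energies) <= starts_e[0] + 1e-9

    def test_no_starts_raise(self, planted):
        fixed, mobile, restraints = planted
        with pytest.raises(DockingError):
            rigid_dock(fixed, mobile, restraints, [])

    def test_deterministic_for_fixed_starts(self, planted):
        fixed, mobile, restraints = planted
        starts = rotation_grid_starts(fixed, mobile, restraints,
                                      n_orientations=48, n_starts=3)
        d1 = rigid_dock(fixed, mobile, restraints, starts)
        d2 = rigid_dock(fixed, mobile, restraints, starts)
        np.testing.assert_array_equal(d1.poses[0].rotation, d2.poses[0].rotation)
        np.testing.assert_array_equal(d1.poses[0].translation,
                                      d2.poses[0].translation)


class TestSelectModel:
    def test_single_candidate_returned_with_scores(self, planted):
        fixed, mobile, restraints = planted
        result = select_model([(fixed, mobile)], restraints)
        assert result.best_index == 0
        assert len(result.table) == 1
        assert {"overlap_score", "restraint_rms"} <= set(result.table[0])

    def test_truth_beats_flipped_decoy(self):
        wins = 0
        n_trials = 12
        for seed in range(n_trials):
            fixed, mobile, restraints = planted_docking_problem(seed + 400)
            flip = RigidPose(
                rotation=np.diag([1.0, -1.0, -1.0]),  # 180° about x
                translation=np.zeros(3))
            decoy = Body(mobile.resnums,
                         flip.apply(mobile.coords, mobile.centroid))
            result = select_model([(fixed, mobile), (fixed, decoy)], restraints)
            wins += result.best_index == 0
        assert wins >= 0.95 * n_trials

    def test_score_table_has_one_row_per_candidate(self, planted):
        fixed, mobile, restraints = planted
        result = select_model([(fixed, mobile)] * 3, restraints)
        assert len(result.table) == 3
        assert result.tie  # identical candidates tie; first wins
        assert result.best_index == 0


class TestClashes:
    def test_clash_count_on_touching_beads(self):
        fixed = Body([1, 2], [[0.0, 0, 0], [10.0, 0, 0]])
        assert count_clashes(fixed, np.array([[1.0, 0, 0]])) == 1
        assert count_clashes(fixed, np.array([[5.0, 0, 0]])) == 0
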