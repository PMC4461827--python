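"""Static kinematic planner: stage rotations, constraint satisfaction, and
the closed-form cases that pin the solution down."""

import json

import numpy as np
import pytest

from gazekin import rotation as rot
from gazekin.frames import (
    AngularPosition2D,
    ScreenTarget,
    angle_between_deg,
    dir_from_angles,
)
from gazekin.planner import (
    EyeHeadState,
    PlannerParams,
    RetinalErrorTarget,
    UnreachableTargetError,
    desired_head_angles,
    displacement_commands,
    fick_orientation_from_dir,
    listing_orientation_from_dir,
    plan_gaze_shift,
    split_rotation,
    vor_rotation,
)

FWD = np.array([1.0, 0.0, 0.0])
REF = EyeHeadState.reference()
DEFAULT = PlannerParams(0.5, 0.5, 0.5)


class TestHeadAngles:
    @pytest.mark.parametrize(
        "b_i, c_d, alpha, beta, expected",
        [
            ((0, 0), (40, 0), 0.5, 0.5, (20, 0)),
            ((0, 0), (30, 20), 1.0, 1.0, (30, 20)),
            ((10, -5), (30, 15), 0.3, 0.6, (16, 7)),
        ],
    )
    def test_interpolation(self, b_i, c_d, alpha, beta, expected):
        out = desired_head_angles(
            AngularPosition2D(*b_i), AngularPosition2D(*c_d), alpha, beta
        )
        assert (out.gamma, out.eta) == pytest.approx(expected, abs=1e-12)

    def test_param_range_enforced(self):
        with pytest.raises(ValueError, match="alpha"):
            PlannerParams(alpha=1.5)
        with pytest.raises(ValueError, match="delta"):
            PlannerParams(delta=-0.1)


class TestConstraintOrientations:
    def test_fick_orientation_points_and_has_zero_torsion(self):
        d = dir_from_angles(AngularPosition2D(30.0, 30.0))
        H = fick_orientation_from_dir(d)
        np.testing.assert_allclose(H @ FWD, d, atol=1e-9)
        fa = rot.fick_angles_of(H)
        assert fa.theta == pytest.approx(30.0, abs=1e-9)
        assert fa.phi == pytest.approx(-30.0, abs=1e-9)
        assert fa.psi == pytest.approx(0.0, abs=1e-12)

    def test_fick_orientation_quaternion_closed_form(self):
        from scipy.spatial.transform import Rotation as ScipyRotation

        d = dir_from_angles(AngularPosition2D(30.0, 30.0))
        qx = ScipyRotation.from_matrix(fick_orientation_from_dir(d)).as_quat()[0]
        expected = -np.sin(np.deg2rad(15.0)) * np.sin(np.deg2rad(-15.0))
        assert qx == pytest.approx(expected, abs=1e-12)  # ~ +0.06699

    def test_reference_directions_give_identity(self):
        np.testing.assert_allclose(fick_orientation_from_dir(FWD), np.eye(3), atol=1e-12)
        np.testing.assert_allclose(listing_orientation_from_dir(FWD), np.eye(3), atol=1e-12)

    @pytest.mark.parametrize(
        "e_d, axis, tau",
        [
            ([np.cos(np.deg2rad(40)), 0, np.sin(np.deg2rad(40))], [0, -1, 0], 40.0),
            ([np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0], [0, 0, 1], 30.0),
        ],
    )
    def test_listing_orientation_axis_convention(self, e_d, axis, tau):
        E = listing_orientation_from_dir(np.asarray(e_d, float))
        aa = rot.axis_angle_of(E)
        np.testing.assert_allclose(aa.axis, axis, atol=1e-9)
        assert aa.angle_deg == pytest.approx(tau, abs=1e-9)
        assert abs(rot.listing_torsion_deg(E)) < 1e-10

    def test_listing_orientation_many_directions(self, rng):
        for _ in range(200):
            p = AngularPosition2D(rng.uniform(-80, 80), rng.uniform(-80, 80))
            e_d = dir_from_angles(p)
            E = listing_orientation_from_dir(e_d)
            np.testing.assert_allclose(E @ FWD, e_d, atol=1e-9)
            assert abs(rot.listing_torsion_deg(E)) < 1e-10

    def test_antiparallel_rejected(self):
        with pytest.raises(UnreachableTargetError):
            listing_orientation_from_dir(np.array([-1.0, 0.0, 0.0]))


class TestSplitAndVor:
    def test_coaxial_split(self):
        Rh, Rw = split_rotation(rot.rot_z(30.0), 0.5)
        np.testing.assert_allclose(Rh, rot.rot_z(15.0), atol=1e-12)
        np.testing.assert_allclose(Rw, rot.rot_z(15.0), atol=1e-12)

    def test_delta_one_puts_all_in_first_phase(self):
        Rt = rot.rot_z(30.0)
        Rh, Rw = split_rotation(Rt, 1.0)
        np.testing.assert_allclose(Rh, Rt, atol=1e-12)
        np.testing.assert_allclose(Rw, np.eye(3), atol=1e-12)

    def test_split_recomposes(self, rng):
        from conftest import random_rotation

        for _ in range(100):
            Rt = random_rotation(rng)
            delta = rng.uniform(0, 1)
            Rh, Rw = split_rotation(Rt, delta)
            np.testing.assert_allclose(Rw @ Rh, Rt, atol=1e-9)

    def test_vor_identity_when_no_second_phase(self):
        Rt = rot.rot_z(30.0)
        Rh, Rw = split_rotation(Rt, 1.0)
        np.testing.assert_allclose(vor_rotation(np.eye(3), Rh, Rw), np.eye(3), atol=1e-12)

    def test_vor_coaxial_closed_form(self):
        Rh, Rw = split_rotation(rot.rot_z(30.0), 0.5)
        np.testing.assert_allclose(
            vor_rotation(np.eye(3), Rh, Rw), rot.rot_z(-15.0), atol=1e-12
        )

    def test_vor_stabilizes_gaze_in_oblique_case(self, seeded_states, seeded_targets):
        for state, tgt in zip(seeded_states[:20], seeded_targets[:20]):
            p = plan_gaze_shift(state, tgt, PlannerParams(0.6, 0.3, 0.7))
            lhs = p.Rw @ p.Rh @ state.H @ p.Rv @ p.Re @ state.E
            rhs = p.Rh @ state.H @ p.Re @ state.E
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestPlanGazeShift:
    def test_center_target_from_reference_is_identity(self):
        p = plan_gaze_shift(REF, ScreenTarget(0.0, 0.0, 100.0), DEFAULT)
        for M in (p.Re, p.Rh, p.Rw, p.Rv, p.Rt, p.Ra, p.E_d, p.H_d, p.G_d):
            np.testing.assert_allclose(M, np.eye(3), atol=1e-12)

    def test_coaxial_60deg_closed_form(self):
        p = plan_gaze_shift(REF, AngularPosition2D(60.0, 0.0), DEFAULT)
        np.testing.assert_allclose(p.Re, rot.rot_z(45.0), atol=1e-12)
        np.testing.assert_allclose(p.Rh, rot.rot_z(15.0), atol=1e-12)
        np.testing.assert_allclose(p.Rw, rot.rot_z(15.0), atol=1e-12)
        np.testing.assert_allclose(p.Rv, rot.rot_z(-15.0), atol=1e-12)
        np.testing.assert_allclose(p.E_d, rot.rot_z(30.0), atol=1e-12)
        np.testing.assert_allclose(p.H_d, rot.rot_z(30.0), atol=1e-12)

    def test_oblique_plan_satisfies_all_postconditions(self):
        p = plan_gaze_shift(REF, AngularPosition2D(40.0, 40.0), DEFAULT)
        assert angle_between_deg(p.G_d @ FWD, p.g_d) < 1e-7
        assert abs(rot.listing_torsion_deg(p.E_d)) < 1e-9
        assert abs(rot.fick_torsion_deg(p.H_d)) < 1e-9
        # saccade alone leaves Listing's plane; the predicted VOR cancels it
        assert abs(rot.listing_torsion_deg(p.Re @ REF.E)) > 0.1
        np.testing.assert_allclose(p.Rv @ (p.Re @ REF.E), p.E_d, atol=1e-12)

    def test_invariants_over_seeded_sweep(self, seeded_states, seeded_targets):
        worst_acc = worst_listing = worst_fick = 0.0
        for state, tgt in zip(seeded_states, seeded_targets):
            for params in (DEFAULT, PlannerParams(0.3, 0.8, 0.2)):
                p = plan_gaze_shift(state, tgt, params)
                worst_acc = max(worst_acc, angle_between_deg(p.G_d @ FWD, p.g_d))
                worst_listing = max(worst_listing, abs(rot.listing_torsion_deg(p.E_d)))
                worst_fick = max(worst_fick, abs(rot.fick_torsion_deg(p.H_d)))
                # stage-composition identities (the four Table rows)
                np.testing.assert_allclose(p.Rt, p.Rw @ p.Rh, atol=1e-9)
                np.testing.assert_allclose(p.Ra, p.Rv @ p.Re, atol=1e-9)
                np.testing.assert_allclose(p.E_d, p.Rv @ p.Re @ state.E, atol=1e-9)
                np.testing.assert_allclose(p.H_d, p.Rw @ p.Rh @ state.H, atol=1e-9)
                np.testing.assert_allclose(p.G_d, p.H_d @ p.E_d, atol=1e-9)
        assert worst_acc < 1e-7
        assert worst_listing < 1e-9
        assert worst_fick < 1e-9

    def test_delta_changes_only_the_saccade_vor_split(self, seeded_states, seeded_targets):
        for state, tgt in zip(seeded_states[:20], seeded_targets[:20]):
            plans = [
                plan_gaze_shift(state, tgt, PlannerParams(0.4, 0.6, d))
                for d in (0.1, 0.5, 0.9)
            ]
            for p in plans[1:]:
                assert np.max(np.abs(p.E_d - plans[0].E_d)) < 1e-12
                assert np.max(np.abs(p.H_d - plans[0].H_d)) < 1e-12
                assert np.max(np.abs(p.G_d - plans[0].G_d)) < 1e-12
            assert np.max(np.abs(plans[0].Re - plans[2].Re)) > 1e-3

    def test_full_head_contribution_returns_eye_to_primary(self, seeded_targets):
        for tgt in seeded_targets[:20]:
            p = plan_gaze_shift(REF, tgt, PlannerParams(1.0, 1.0, 0.5))
            np.testing.assert_allclose(p.E_d, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(p.H_d @ FWD, p.g_d, atol=1e-9)

    def test_zero_head_contribution_is_head_fixed_saccade(self, seeded_states, seeded_targets):
        for state, tgt in zip(seeded_states[:20], seeded_targets[:20]):
            p = plan_gaze_shift(state, tgt, PlannerParams(0.0, 0.0, 0.5))
            np.testing.assert_allclose(p.H_d, state.H, atol=1e-9)
            np.testing.assert_allclose(p.Rt, np.eye(3), atol=1e-9)

    def test_retinal_error_input_mode(self):
        g_re = dir_from_angles(AngularPosition2D(60.0, 0.0))
        E_i = listing_orientation_from_dir(dir_from_angles(AngularPosition2D(20.0, 0.0)))
        state = EyeHeadState(E_i, np.eye(3))
        p = plan_gaze_shift(state, RetinalErrorTarget(g_re), DEFAULT)
        # coaxial: initial gaze 20 deg plus 60 deg retinal error -> 80 deg target
        from gazekin.frames import angles_from_dir

        assert angles_from_dir(p.g_d).gamma == pytest.approx(80.0, abs=1e-9)

    def test_unreachable_target_raises(self):
        E_i = listing_orientation_from_dir(dir_from_angles(AngularPosition2D(80.0, 0.0)))
        state = EyeHeadState(E_i, np.eye(3))
        g_re = dir_from_angles(AngularPosition2D(60.0, 0.0))  # 140 deg total
        with pytest.raises(UnreachableTargetError):
            plan_gaze_shift(state, RetinalErrorTarget(g_re), DEFAULT)


class TestDisplacements:
    def test_identity_plan_has_zero_commands(self):
        p = plan_gaze_shift(REF, ScreenTarget(0.0, 0.0), DEFAULT)
        dE, dH = displacement_commands(p, REF)
        np.testing.assert_allclose(dE, 0.0, atol=1e-12)
        np.testing.assert_allclose(dH, 0.0, atol=1e-12)

    def test_coaxial_head_command(self):
        p = plan_gaze_shift(REF, AngularPosition2D(60.0, 0.0), DEFAULT)
        _, dH = displacement_commands(p, REF)
        np.testing.assert_allclose(dH, [0.0, 0.0, np.deg2rad(30.0)], atol=1e-12)

    def test_eye_command_reconstructs_post_saccadic_direction(self, seeded_states, seeded_targets):
        from gazekin.rotation import rotation_from_rotvec, rotvec_of

        for state, tgt in zip(seeded_states[:20], seeded_targets[:20]):
            p = plan_gaze_shift(state, tgt, DEFAULT)
            dE, _ = displacement_commands(p, state)
            E_target = rotation_from_rotvec(rotvec_of(state.E) + dE)
            np.testing.assert_allclose(
                E_target @ FWD, p.Re @ state.E @ FWD, atol=1e-9
            )

    def test_plan_serialization_is_json(self):
        p = plan_gaze_shift(REF, AngularPosition2D(30.0, 10.0), DEFAULT)
        record = json.loads(json.dumps(p.to_dict()))
        assert record["schema"] == "gazekin.plan/1"
        np.testing.assert_allclose(np.array(record["desired"]["E_d"]), p.E_d)
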