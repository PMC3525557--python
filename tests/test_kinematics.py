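"""Forward model: segment poses, CoM, task variables, Jacobian, inverse."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitcov.model import (
    SIDES,
    TASK_VARIABLES,
    JointSpec,
    KinematicModel,
    SegmentSpec,
    TaskDefinition,
    compute_com,
    compute_task_variables,
    extract_joint_angles,
    forward_kinematics,
    numerical_jacobian,
    task_jacobian,
    task_variables_from_points,
)


class TestForwardKinematics:
    def test_zero_angles_give_reference_posture(self, model):
        poses = forward_kinematics(model, np.zeros(model.d))
        for sid in model.segments:
            assert np.allclose(poses.rot[sid], np.eye(3), atol=1e-15)
        # head origin = accumulated joint offsets up the trunk chain
        assert np.allclose(poses.trans["head"], [0.0, 0.0, 0.65], atol=1e-15)
        assert np.allclose(poses.trans["foot_l"], [0.0, 0.09, -0.90], atol=1e-15)

    def test_planar_two_link_trigonometry(self, planar_model):
        # hip flexion 30 deg, knee 0: endpoint 0.8*sin(30) = 0.4 m forward
        theta = np.zeros(3)
        theta[0] = np.deg2rad(30.0)
        poses = forward_kinematics(planar_model, theta)
        tip = poses.marker_position(planar_model, "LTIP")
        root = poses.trans["base"]
        assert tip[0] - root[0] == pytest.approx(0.4, abs=1e-12)
        assert tip[2] - root[2] == pytest.approx(-0.8 * np.cos(np.deg2rad(30)), abs=1e-12)

    @pytest.mark.parametrize("a_deg,b_deg", [(15, 25), (-20, 40), (35, -10)])
    def test_planar_endpoint_closed_form(self, planar_model, a_deg, b_deg):
        a, b = np.deg2rad([a_deg, b_deg])
        theta = np.array([a, b, 0.0])
        tip = forward_kinematics(planar_model, theta).marker_position(
            planar_model, "LTIP"
        )
        assert tip[0] == pytest.approx(0.4 * np.sin(a) + 0.4 * np.sin(a + b), abs=1e-12)

    def test_rejects_bad_theta(self, model):
        with pytest.raises(ValueError, match="entries"):
            forward_kinematics(model, np.zeros(model.d - 1))
        bad = np.zeros(model.d)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            forward_kinematics(model, bad)

    def test_batched_matches_loop(self, model, rng):
        thetas = rng.uniform(-0.4, 0.4, (5, model.d))
        batch = forward_kinematics(model, thetas)
        for i in range(5):
            single = forward_kinematics(model, thetas[i])
            for sid in model.segments:
                assert np.allclose(batch.rot[sid][i], single.rot[sid], atol=1e-14)
                assert np.allclose(batch.trans[sid][i], single.trans[sid], atol=1e-14)


class TestAngleExtraction:
    def test_identity_poses_give_zero_angles(self, model):
        poses = forward_kinematics(model, np.zeros(model.d))
        assert np.allclose(extract_joint_angles(poses, model), 0.0, atol=1e-15)

    def test_fk_ik_roundtrip(self, model, rng):
        for _ in range(20):
            theta = rng.uniform(-np.pi / 2 * 0.9, np.pi / 2 * 0.9, model.d)
            rec = extract_joint_angles(forward_kinematics(model, theta), model)
            assert np.abs(rec - theta).max() < 1e-10

    def test_cardan_recomposition_reproduces_poses(self, model, rng):
        theta = rng.uniform(-1.0, 1.0, model.d)
        poses = forward_kinematics(model, theta)
        rec = extract_joint_angles(poses, model)
        poses2 = forward_kinematics(model, rec)
        for sid in model.segments:
            assert np.allclose(poses.rot[sid], poses2.rot[sid], atol=1e-12)
            assert np.allclose(poses.trans[sid], poses2.trans[sid], atol=1e-12)

    def test_single_axis_rotation(self, model):
        # pure 25 deg rotation about the hip's first Cardan axis
        theta = np.zeros(model.d)
        theta[model.dof_slices["hip_l"].start] = np.deg2rad(25.0)
        rec = extract_joint_angles(forward_kinematics(model, theta), model)
        assert rec[model.dof_slices["hip_l"]] == pytest.approx(
            [np.deg2rad(25.0), 0.0, 0.0], abs=1e-12
        )

    def test_gimbal_lock_flagged(self, model):
        theta = np.zeros(model.d)
        sl = model.dof_slices["hip_l"]  # 3-DOF Cardan joint
        theta[sl.start + 1] = np.pi / 2  # middle axis at the singularity
        poses = forward_kinematics(model, theta)
        rec, report = extract_joint_angles(poses, model, return_report=True)
        assert "hip_l" in report.gimbal_joints
        assert np.all(np.isfinite(rec))

    def test_missing_pose_rejected(self, model):
        poses = forward_kinematics(model, np.zeros(model.d))
        del poses.rot["head"]
        with pytest.raises(ValueError, match="missing"):
            extract_joint_angles(poses, model)


class TestCenterOfMass:
    def test_equal_mass_midpoint(self):
        segs = [
            SegmentSpec("a", 2.0, [0, 0, 1], 0.5, 0.5, {"A": [0, 0, 0]}),
            SegmentSpec("b", 2.0, [0, 0, 1], 0.5, 0.5, {"B": [0, 0, 0]}),
        ]
        joints = [JointSpec("j", "a", "b", [1.0, 0.0, 0.0], ("x",))]
        task = {s: {"heel": "A", "toe": "B"} for s in SIDES}
        m = KinematicModel(segs, joints, "a", task)
        poses = forward_kinematics(m, np.zeros(1))
        # segment CoMs at (0,0,1) and (1,0,1)
        assert np.allclose(compute_com(m, poses), [0.5, 0.0, 1.0], atol=1e-15)

    def test_matches_bruteforce_resummation(self, model, rng):
        theta = rng.uniform(-0.5, 0.5, model.d)
        poses = forward_kinematics(model, theta)
        expected = sum(
            seg.mass_fraction * poses.point(seg.id, seg.axis * seg.length * seg.com_offset)
            for seg in model.segments.values()
        )
        assert np.allclose(compute_com(model, poses), expected, atol=1e-12)

    def test_translation_moves_com_exactly(self, model, rng):
        theta = rng.uniform(-0.5, 0.5, model.d)
        poses = forward_kinematics(model, theta)
        v = np.array([0.3, -1.2, 0.7])
        com0 = compute_com(model, poses)
        com1 = compute_com(model, poses.translated(v))
        assert np.allclose(com1 - com0, v, atol=1e-12)

    def test_missing_segment_rejected(self, model):
        poses = forward_kinematics(model, np.zeros(model.d))
        del poses.rot["hand_l"]
        with pytest.raises(ValueError, match="missing"):
            compute_com(model, poses)


class TestTaskVariables:
    def test_additivity_exact(self, model, rng):
        for side in SIDES:
            theta = rng.uniform(-0.5, 0.5, (10, model.d))
            tv = compute_task_variables(model, theta, side)
            assert np.abs(tv[:, 0] - (tv[:, 2] + tv[:, 4])).max() <= 1e-12
            assert np.abs(tv[:, 1] - (tv[:, 3] + tv[:, 5])).max() <= 1e-12

    def test_constructed_geometry(self):
        # front heel 0.60 m ahead of the back toe, CoM 0.35 m ahead of it
        tv = task_variables_from_points(
            back_toe=np.array([0.0, 0.0, 0.0]),
            front_heel=np.array([0.60, 0.10, 0.02]),
            com=np.array([0.35, 0.06, 0.95]),
            front_side="left",
        )
        named = dict(zip(TASK_VARIABLES, tv))
        assert named["stepX"] == pytest.approx(0.60, abs=1e-12)
        assert named["bCoMX"] == pytest.approx(0.35, abs=1e-12)
        assert named["fCoMX"] == pytest.approx(0.25, abs=1e-12)

    def test_lateral_axis_mirrors_with_front_side(self):
        bt = np.array([0.0, 0.0, 0.0])
        fh = np.array([0.6, 0.1, 0.0])
        com = np.array([0.3, 0.04, 1.0])
        left = task_variables_from_points(bt, fh, com, "left")
        right = task_variables_from_points(bt, fh, com, "right")
        assert left[1] == pytest.approx(-right[1], abs=1e-15)  # stepY flips
        assert left[0] == pytest.approx(right[0], abs=1e-15)  # stepX does not

    def test_symmetric_standing_com_is_midline(self, model):
        tv_com = compute_com(model, forward_kinematics(model, np.zeros(model.d)))
        assert tv_com[1] == pytest.approx(0.0, abs=1e-12)

    def test_global_translation_invariance(self, model, rng):
        theta = rng.uniform(-0.4, 0.4, model.d)
        a = compute_task_variables(model, theta, "left")
        b = compute_task_variables(
            model, theta, "left", root_trans=np.array([5.0, -2.0, 0.4])
        )
        assert np.allclose(a, b, atol=1e-12)

    def test_invalid_side_rejected(self, model):
        with pytest.raises(ValueError, match="side"):
            compute_task_variables(model, np.zeros(model.d), "up")


class TestJacobian:
    def test_planar_analytic_gradient(self, planar_model):
        a, b = np.deg2rad([20.0, 35.0])
        theta = np.array([a, b, 0.0])
        J = task_jacobian(planar_model, theta, "left")
        d_hip = 0.4 * np.cos(a) + 0.4 * np.cos(a + b)
        d_knee = 0.4 * np.cos(a + b)
        # stepX = front-heel x - back-toe x; only the left chain moves it
        assert J[0, 0] == pytest.approx(d_hip, abs=1e-8)
        assert J[0, 1] == pytest.approx(d_knee, abs=1e-8)

    def test_disconnected_dof_zero_gradient(self, model, step_theta):
        # stepX depends only on foot markers: wrist angles cannot move it
        row = numerical_jacobian(
            model, step_theta, TaskDefinition("stepX", "left")
        ).gradient
        for wrist in ("wrist_l", "wrist_r"):
            assert np.allclose(row[model.dof_slices[wrist]], 0.0, atol=1e-10)

    def test_step_size_convergence(self, model, step_theta):
        J1 = task_jacobian(model, step_theta, "left", step_size=1e-4)
        J2 = task_jacobian(model, step_theta, "left", step_size=5e-5)
        assert np.abs(J1 - J2).max() < 1e-6

    def test_rejects_nonpositive_step(self, model, step_theta):
        with pytest.raises(ValueError, match="step_size"):
            task_jacobian(model, step_theta, "left", step_size=0.0)

    def test_linearization_quality_2deg(self, model, step_theta, rng):
        J = task_jacobian(model, step_theta, "left")
        base = compute_task_variables(model, step_theta, "left")
        delta = rng.uniform(-np.deg2rad(2), np.deg2rad(2), (50, model.d))
        pred = base + delta @ J.T
        actual = compute_task_variables(model, step_theta + delta, "left")
        assert np.abs(actual - pred).max() <= 1e-3  # 1 mm


def test_default_configuration_counts(model):
    assert model.d == 35
    assert model.n_joints == 15
    assert len(TASK_VARIABLES) == 6
    assert sum(s.mass_fraction for s in model.segments.values()) == pytest.approx(
        1.0, abs=1e-9
    )
    assert len(model.joint_blocks) == 15
    assert sum(len(b) for b in model.joint_blocks) == 35


def test_rotation_order_sign_convention():
    # '-y' flips the rotation sense relative to 'y'
    j_pos = JointSpec("j", "a", "b", [0, 0, 0], ("y",))
    j_neg = JointSpec("j", "a", "b", [0, 0, 0], ("-y",))
    from gaitcov.model import _joint_rotation

    ang = np.array([0.3])
    assert np.allclose(
        _joint_rotation(j_pos, ang), _joint_rotation(j_neg, -ang), atol=1e-15
    )
    assert np.allclose(
        _joint_rotation(j_pos, ang), Rotation.from_euler("y", 0.3).as_matrix()
    )
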