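"""Arm/hand kinematics: FK identities, Jacobian correctness, IK round trips."""

import numpy as np
import pytest

from bimanip.kinematics import (
    ArmFit,
    arm_jacobian,
    arm_marker_frame,
    contact_point_jacobian,
    fk_arm,
    grasp_map,
    hand_joint_angles,
    hand_marker_frame,
    hand_marker_local,
    hand_object_jacobian,
    ik_arm,
    joint_torques,
    stacked_contact_jacobian,
)
from bimanip.skeleton import (
    ArmSkeleton,
    Contact,
    ContactSet,
    HandSkeleton,
    MarkerError,
    MarkerFrame,
    RigidFrame,
    SkeletonError,
)

from conftest import random_in_limit_q


class TestArmForwardKinematics:
    def test_link_lengths_conserved(self, arm, rng):
        """Pairwise joint distances equal the declared link lengths."""
        for _ in range(20):
            q = random_in_limit_q(arm, rng)
            _, joints = fk_arm(arm, q)
            L1, L2, L3 = arm.lengths
            assert abs(np.linalg.norm(joints["p_elbow"] - joints["p_shoulder"]) - L1) < 1e-9
            assert abs(np.linalg.norm(joints["p_wrist"] - joints["p_elbow"]) - L2) < 1e-9
            assert abs(np.linalg.norm(joints["p_palm"] - joints["p_wrist"]) - L3) < 1e-9

    def test_elbow_at_shoulder_distance(self, arm):
        q = arm.rest_posture.copy()
        _, joints = fk_arm(arm, q)
        assert abs(np.linalg.norm(joints["p_elbow"] - joints["p_shoulder"])
                   - arm.link_lengths["upper_arm"]) < 1e-12

    def test_planar_two_link_geometry(self):
        """Elbow at 90 deg, everything else zero: closed-form 2-link check."""
        skel = ArmSkeleton(joint_limits=np.deg2rad(
            [(-45, 120), (-60, 60), (-60, 90), (0, 150), (-80, 80),
             (-70, 80), (-30, 20)]),
            rest_posture=np.deg2rad([15, 10, 25, 80, 10, -10, 0]))
        q = np.zeros(7)
        q[3] = np.pi / 2
        _, joints = fk_arm(skel, q)
        L1, L2, _ = skel.lengths
        # upper arm straight down, forearm rotated 90 deg about local +Y
        expected_wrist = np.array([-L2, 0.0, -L1])
        assert np.allclose(joints["p_wrist"], expected_wrist, atol=1e-12)

    def test_end_effector_at_palm(self, arm, rng):
        q = random_in_limit_q(arm, rng)
        frame, joints = fk_arm(arm, q)
        assert np.allclose(frame.translation, joints["p_palm"])

    def test_out_of_limit_rejected_with_joint_index(self, arm):
        q = arm.rest_posture.copy()
        q[3] = arm.joint_limits[3, 1] + 0.2
        with pytest.raises(SkeletonError, match="joint 3"):
            fk_arm(arm, q)


class TestArmJacobian:
    def test_matches_central_differences(self, arm, rng):
        """Each column equals the numeric derivative of the palm position."""
        eps = 1e-7
        for _ in range(50):
            q = random_in_limit_q(arm, rng)
            J = arm_jacobian(arm, q)
            for j in range(7):
                qp, qm = q.copy(), q.copy()
                qp[j] += eps
                qm[j] -= eps
                dp = (fk_arm(arm, qp, check_limits=False)[0].translation
                      - fk_arm(arm, qm, check_limits=False)[0].translation)
                assert np.allclose(J[:3, j], dp / (2 * eps), atol=1e-5)

    def test_revolute_column_identity(self, arm, rng):
        """Linear rows are axis x (p_ee - p_joint); angular rows are the axis."""
        q = random_in_limit_q(arm, rng)
        J = arm_jacobian(arm, q)
        # angular columns are unit axes
        assert np.allclose(np.linalg.norm(J[3:], axis=0), 1.0, atol=1e-12)
        # column 3 (elbow): axis x (palm - elbow)
        frame, joints = fk_arm(arm, q)
        col = np.cross(J[3:, 3], joints["p_palm"] - joints["p_elbow"])
        assert np.allclose(J[:3, 3], col, atol=1e-12)

    def test_outstretched_posture_is_singular(self):
        skel = ArmSkeleton(joint_limits=np.deg2rad(
            [(-45, 120), (-60, 60), (-60, 90), (0, 150), (-80, 80),
             (-70, 80), (-30, 20)]),
            rest_posture=np.deg2rad([15, 10, 25, 80, 10, -10, 0]))
        J = arm_jacobian(skel, np.zeros(7))
        assert np.linalg.matrix_rank(J[:3], tol=1e-9) < 3


class TestArmInverseKinematics:
    def test_round_trip_noiseless(self, arm, rng):
        """FK markers of a random posture are refit to < 1e-4 rad."""
        worst = 0.0
        for _ in range(40):
            q = random_in_limit_q(arm, rng)
            fit = ik_arm(arm, arm_marker_frame(arm, q))
            worst = max(worst, float(np.max(np.abs(fit.q - q))))
            assert fit.residual < 1e-6
            assert not fit.degenerate and not fit.underdetermined
        assert worst < 1e-4

    def test_joint_limits_respected(self, arm, rng):
        for _ in range(10):
            q = random_in_limit_q(arm, rng)
            fit = ik_arm(arm, arm_marker_frame(arm, q))
            assert not arm.check_limits(fit.q).any()

    def test_noisy_markers_residual_matches_noise_scale(self, arm, rng):
        scale = 1.63e-3
        residuals = []
        for _ in range(15):
            q = random_in_limit_q(arm, rng, margin=0.1)
            mf = arm_marker_frame(arm, q)
            noisy = MarkerFrame({k: v + rng.normal(0, scale / np.sqrt(3), 3)
                                 for k, v in mf.positions.items()})
            residuals.append(ik_arm(arm, noisy).residual)
        mean_res = np.mean(residuals)
        assert 0.2 * scale < mean_res < 3.0 * scale

    def test_missing_marker_raises_by_name(self, arm):
        mf = arm_marker_frame(arm, arm.rest_posture)
        del mf.positions["elbow"]
        with pytest.raises(MarkerError, match="elbow"):
            ik_arm(arm, mf)

    def test_degenerate_collinear_markers_flagged_not_crashing(self, arm):
        z = np.array([0.0, 0.0, 1.0])
        mf = MarkerFrame({
            "shoulder": 0.0 * z, "elbow": -0.30 * z, "wrist": -0.56 * z,
            "hand_center": -0.64 * z})
        fit = ik_arm(arm, mf)
        assert isinstance(fit, ArmFit)
        assert fit.degenerate
        assert np.isfinite(fit.residual)

    def test_single_wrist_marker_is_underdetermined(self, arm, rng):
        q = random_in_limit_q(arm, rng)
        mf = arm_marker_frame(arm, q)
        _, joints = fk_arm(arm, q)
        reduced = MarkerFrame({
            "shoulder": mf["shoulder"], "elbow": mf["elbow"],
            "wrist": joints["p_wrist"], "hand_center": mf["hand_center"]})
        fit = ik_arm(arm, reduced)
        assert fit.underdetermined

    def test_inconsistent_geometry_reports_large_residual(self, arm):
        mf = arm_marker_frame(arm, arm.rest_posture)
        mf.positions["hand_center"] = mf["hand_center"] + np.array([0.2, 0, 0])
        fit = ik_arm(arm, mf)
        assert fit.residual > 0.01


class TestHandModel:
    def test_straight_fingers_have_zero_flexion(self, hand):
        q = np.zeros(20)
        frame = RigidFrame.identity()
        markers = hand_marker_frame(hand, q, frame)
        # palm basis needs wrist markers: borrow arm convention
        from bimanip.skeleton import WRIST_MARKER_OFFSET, WRIST_MARKER_SPACING
        w, s = WRIST_MARKER_OFFSET, WRIST_MARKER_SPACING
        wrist = np.array([0.0, 0.0, hand.phalanx_lengths["middle"][0] + 0.04])
        for name, off in (("wrist_radius_1", [w, 0, -s / 2]),
                          ("wrist_radius_2", [w, 0, s / 2]),
                          ("wrist_ulna_1", [-w, 0, -s / 2]),
                          ("wrist_ulna_2", [-w, 0, s / 2])):
            markers.positions[name] = wrist + np.array(off, dtype=float)
        fit = hand_joint_angles(hand, markers)
        assert not fit.missing_fingers
        finite = fit.angles[~np.isnan(fit.angles)]
        # flexion angles at zero pose are zero (up to limit clipping)
        raw_zero = np.isclose(fit.angles, 0.0, atol=1e-6) | fit.clipped
        assert raw_zero.all()

    def _markers_with_wrist(self, hand, q):
        from bimanip.skeleton import WRIST_MARKER_OFFSET, WRIST_MARKER_SPACING
        markers = hand_marker_frame(hand, q, RigidFrame.identity())
        w, s = WRIST_MARKER_OFFSET, WRIST_MARKER_SPACING
        wrist = np.array([0.0, 0.0, 0.08])
        for name, off in (("wrist_radius_1", [w, 0, -s / 2]),
                          ("wrist_radius_2", [w, 0, s / 2]),
                          ("wrist_ulna_1", [-w, 0, -s / 2]),
                          ("wrist_ulna_2", [-w, 0, s / 2])):
            markers.positions[name] = wrist + np.array(off, dtype=float)
        return markers

    def test_ninety_degree_pip_flexion_recovered(self, hand):
        q = np.zeros(20)
        pip_index = hand.finger_slice("index").start + 2
        q[pip_index] = np.pi / 2
        fit = hand_joint_angles(hand, self._markers_with_wrist(hand, q))
        assert abs(fit.angles[pip_index] - np.pi / 2) < 1e-3

    def test_round_trip_random_pose(self, hand, rng):
        lo, hi = hand.joint_limits[:, 0], hand.joint_limits[:, 1]
        q = lo + (hi - lo) * rng.uniform(0.1, 0.9, 20)
        fit = hand_joint_angles(hand, self._markers_with_wrist(hand, q))
        assert np.allclose(fit.angles, q, atol=1e-9)
        assert not fit.clipped.any()

    def test_out_of_limit_angle_clipped_and_flagged(self, hand):
        q = np.zeros(20)
        pip_index = hand.finger_slice("index").start + 2
        q_violating = q.copy()
        # build markers from a raw pose beyond the PIP limit
        q_free = q.copy()
        q_free[pip_index] = hand.joint_limits[pip_index, 1] + 0.3
        markers = self._markers_with_wrist(hand, q_free)
        fit = hand_joint_angles(hand, markers)
        assert fit.clipped[pip_index]
        assert fit.angles[pip_index] == pytest.approx(
            hand.joint_limits[pip_index, 1])

    def test_missing_finger_absent_and_flagged(self, hand):
        markers = self._markers_with_wrist(hand, np.zeros(20))
        for n in ("ring_pip", "ring_dip"):
            del markers.positions[n]
        fit = hand_joint_angles(hand, markers)
        assert "ring" in fit.missing_fingers
        assert np.isnan(fit.angles[hand.finger_slice("ring")]).all()
        with pytest.raises(SkeletonError):
            fit.joint_vector


class TestHandObjectJacobian:
    def _fingertip_contact(self, hand, q=None):
        q = np.zeros(20) if q is None else q
        local = hand_marker_local(hand, q)
        tip = local["index_tip"]
        return Contact(finger="index", phalanx=2, position=tip,
                       normal=np.array([0.0, 1.0, 0.0]))

    def test_torque_identity_tau_equals_Ht_f(self, hand, rng):
        """tau = H^T f holds against the explicit contact-chain computation."""
        q = hand.rest_posture.copy()
        contacts = ContactSet([
            self._fingertip_contact(hand, q),
            Contact("thumb", 2, hand_marker_local(hand, q)["thumb_tip"],
                    normal=np.array([0.0, -1.0, 0.0]))])
        tool = RigidFrame(np.eye(3), np.array([0.02, 0.01, -0.09]))
        H = hand_object_jacobian(hand, q, contacts, tool)
        Jh = stacked_contact_jacobian(hand, q, contacts)
        G = grasp_map(contacts, tool)
        for _ in range(5):
            f = rng.standard_normal(6)
            lam = np.linalg.pinv(G) @ f
            assert np.allclose(joint_torques(H, f), Jh.T @ lam, atol=1e-10)

    def test_single_contact_moment_arm(self, hand):
        """Straight index finger, tip contact, palmar force: the DIP torque
        is the distal phalanx length times the force."""
        q = np.zeros(20)
        contact = self._fingertip_contact(hand, q)
        Jc = contact_point_jacobian(hand, q, contact)
        dip_col = hand.finger_slice("index").start + 3
        f = np.array([0.0, 1.0, 0.0])  # unit palmar force at the tip
        tau_dip = Jc[:3, dip_col] @ f
        Ld = hand.phalanx_lengths["index"][2]
        assert tau_dip == pytest.approx(Ld, abs=1e-12)

    def test_duplicate_contact_doubles_contact_gram_matrix(self, hand):
        q = hand.rest_posture.copy()
        c = self._fingertip_contact(hand, q)
        J1 = stacked_contact_jacobian(hand, q, ContactSet([c]))
        J2 = stacked_contact_jacobian(hand, q, ContactSet([c, c]))
        assert np.allclose(J2.T @ J2, 2.0 * (J1.T @ J1), atol=1e-12)

    def test_normal_flip_preserves_force_rows(self, hand):
        """Rotating the contact frame 180 deg about its normal (normal flip
        here) keeps the 3 transmitted force rows; only the torque row's sign
        follows the normal."""
        q = hand.rest_posture.copy()
        c = self._fingertip_contact(hand, q)
        c_flipped = Contact(c.finger, c.phalanx, c.position, -c.normal)
        J = stacked_contact_jacobian(hand, q, ContactSet([c]))
        Jf = stacked_contact_jacobian(hand, q, ContactSet([c_flipped]))
        assert np.allclose(J[:3], Jf[:3], atol=1e-12)
        assert np.allclose(J[3], -Jf[3], atol=1e-12)

    def test_empty_contact_set_rejected(self):
        with pytest.raises(SkeletonError):
            ContactSet([])
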