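"""Forward/inverse kinematics for the arm and hand skeleton models.

The arm chain (see :mod:`bimanip.skeleton` for the axis convention) is

    R_sh = Rx(q0) Rz(q1) Ry(q2)            shoulder
    p_E  = p_S + R_sh (0, 0, -L_ua)
    R_4  = R_sh Ry(q3)                     elbow
    p_W  = p_E + R_4 (0, 0, -L_fa)
    R_5  = R_4 Rz(q4)                      forearm pronation
    R_6  = R_5 Ry(q5)                      wrist flexion
    R_7  = R_6 Rx(q6)                      ulnar/radial deviation
    p_P  = p_W + R_7 (0, 0, -L_h)          palm centre = end effector

The end-effector frame (R_7, p_P) coincides with the hand model's base
frame.  Inverse kinematics is solved in closed form from the marker
geometry and refined by bounded least squares with a small
deviation-from-rest regularizer, which makes the solution unique.

Forearm pronation is observable only through the ulna/radius wrist
trackers (two on each bone, straddling the wrist centre); with a single
wrist marker the chain has a one-dimensional null space (rotation about
the wrist->palm axis) and the fit is flagged ``underdetermined``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .skeleton import (
    ARM_DOF,
    FINGERS,
    HAND_DOF,
    N_JOINTS_PER_FINGER,
    WRIST_MARKER_OFFSET,
    WRIST_MARKER_SPACING,
    ArmSkeleton,
    Contact,
    ContactSet,
    HandSkeleton,
    JointVector,
    MarkerError,
    MarkerFrame,
    RigidFrame,
    SkeletonError,
)

ARM_IK_MARKERS = ("shoulder", "elbow", "hand_center")
WRIST_MARKERS = ("wrist_radius_1", "wrist_radius_2", "wrist_ulna_1", "wrist_ulna_2")

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# batched rotation helpers
# ---------------------------------------------------------------------------

def _rot_batch(angle: np.ndarray, axis: str) -> np.ndarray:
    """Elementary rotation matrices, shape (..., 3, 3)."""
    a = np.asarray(angle, dtype=float)
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    if axis == "x":
        R[..., 0, 0] = 1.0
        R[..., 1, 1] = c
        R[..., 1, 2] = -s
        R[..., 2, 1] = s
        R[..., 2, 2] = c
    elif axis == "y":
        R[..., 0, 0] = c
        R[..., 0, 2] = s
        R[..., 1, 1] = 1.0
        R[..., 2, 0] = -s
        R[..., 2, 2] = c
    elif axis == "z":
        R[..., 0, 0] = c
        R[..., 0, 1] = -s
        R[..., 1, 0] = s
        R[..., 1, 1] = c
        R[..., 2, 2] = 1.0
    else:  # pragma: no cover
        raise ValueError(axis)
    return R


def _fk_arm_batch(skeleton: ArmSkeleton, Q: np.ndarray) -> Dict[str, np.ndarray]:
    """Vectorized forward kinematics over leading batch dimensions of Q."""
    Q = np.asarray(Q, dtype=float)
    L1, L2, L3 = skeleton.lengths
    p_S = skeleton.shoulder_position

    Rx0 = _rot_batch(Q[..., 0], "x")
    Rz1 = _rot_batch(Q[..., 1], "z")
    Ry2 = _rot_batch(Q[..., 2], "y")
    R_sh = Rx0 @ Rz1 @ Ry2
    p_E = p_S + R_sh @ (-L1 * _EZ)

    R4 = R_sh @ _rot_batch(Q[..., 3], "y")
    p_W = p_E + R4 @ (-L2 * _EZ)

    R5 = R4 @ _rot_batch(Q[..., 4], "z")
    R6 = R5 @ _rot_batch(Q[..., 5], "y")
    R7 = R6 @ _rot_batch(Q[..., 6], "x")
    p_P = p_W + R7 @ (-L3 * _EZ)

    return {
        "p_shoulder": np.broadcast_to(p_S, p_P.shape),
        "p_elbow": p_E,
        "p_wrist": p_W,
        "p_palm": p_P,
        "R_sh": R_sh,
        "R4": R4,
        "R5": R5,
        "R6": R6,
        "R7": R7,
        "Rx0": Rx0,
        "Rz1": Rz1,
    }


def _arm_axes_batch(fk: Dict[str, np.ndarray]) -> np.ndarray:
    """World-frame joint axes, shape (..., 7, 3)."""
    batch = fk["p_palm"].shape[:-1]
    axes = np.empty(batch + (ARM_DOF, 3))
    axes[..., 0, :] = _EX
    axes[..., 1, :] = fk["Rx0"] @ _EZ
    axes[..., 2, :] = (fk["Rx0"] @ fk["Rz1"]) @ _EY
    axes[..., 3, :] = fk["R_sh"] @ _EY
    axes[..., 4, :] = fk["R4"] @ _EZ
    axes[..., 5, :] = fk["R5"] @ _EY
    axes[..., 6, :] = fk["R6"] @ _EX
    return axes


def _arm_jacobian_batch(skeleton: ArmSkeleton, Q: np.ndarray,
                        fk: Optional[Dict[str, np.ndarray]] = None) -> np.ndarray:
    """Spatial Jacobian (..., 6, 7): linear rows then angular rows."""
    if fk is None:
        fk = _fk_arm_batch(skeleton, Q)
    axes = _arm_axes_batch(fk)
    batch = fk["p_palm"].shape[:-1]
    pivots = np.empty(batch + (ARM_DOF, 3))
    for j, key in enumerate(("p_shoulder",) * 3 + ("p_elbow",) + ("p_wrist",) * 3):
        pivots[..., j, :] = fk[key]
    arm = fk["p_palm"][..., None, :] - pivots
    J = np.empty(batch + (6, ARM_DOF))
    J[..., :3, :] = np.swapaxes(np.cross(axes, arm), -1, -2)
    J[..., 3:, :] = np.swapaxes(axes, -1, -2)
    return J


# ---------------------------------------------------------------------------
# public scalar API
# ---------------------------------------------------------------------------

def fk_arm(skeleton: ArmSkeleton, q: JointVector | np.ndarray,
           check_limits: bool = True) -> Tuple[RigidFrame, Dict[str, np.ndarray]]:
    """Forward kinematics: end-effector frame and per-joint world positions."""
    qa = q.angles if isinstance(q, JointVector) else np.asarray(q, dtype=float)
    if qa.shape != (ARM_DOF,):
        raise SkeletonError(f"arm FK expects 7 angles, got shape {qa.shape}")
    if check_limits:
        skeleton.assert_within_limits(qa)
    fk = _fk_arm_batch(skeleton, qa)
    frame = RigidFrame(fk["R7"], fk["p_palm"])
    joints = {k: fk[k] for k in ("p_shoulder", "p_elbow", "p_wrist", "p_palm")}
    return frame, joints


def arm_marker_frame(skeleton: ArmSkeleton, q: JointVector | np.ndarray,
                     check_limits: bool = True) -> MarkerFrame:
    """Noise-free model marker positions for a posture (the IK marker set)."""
    qa = q.angles if isinstance(q, JointVector) else np.asarray(q, dtype=float)
    if check_limits:
        skeleton.assert_within_limits(qa)
    fk = _fk_arm_batch(skeleton, qa)
    w, s = WRIST_MARKER_OFFSET, WRIST_MARKER_SPACING
    R5, p_W = fk["R5"], fk["p_wrist"]
    pos = {
        "shoulder": fk["p_shoulder"],
        "elbow": fk["p_elbow"],
        "hand_center": fk["p_palm"],
        "wrist_radius_1": p_W + R5 @ np.array([w, 0.0, -s / 2]),
        "wrist_radius_2": p_W + R5 @ np.array([w, 0.0, s / 2]),
        "wrist_ulna_1": p_W + R5 @ np.array([-w, 0.0, -s / 2]),
        "wrist_ulna_2": p_W + R5 @ np.array([-w, 0.0, s / 2]),
    }
    return MarkerFrame(pos)


def arm_jacobian(skeleton: ArmSkeleton, q: JointVector | np.ndarray,
                 check_limits: bool = True) -> np.ndarray:
    """6x7 spatial Jacobian of the palm centre (linear rows, then angular)."""
    qa = q.angles if isinstance(q, JointVector) else np.asarray(q, dtype=float)
    if qa.shape != (ARM_DOF,):
        raise SkeletonError(f"arm Jacobian expects 7 angles, got shape {qa.shape}")
    if check_limits:
        skeleton.assert_within_limits(qa)
    return _arm_jacobian_batch(skeleton, qa)


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

@dataclass
class ArmFit:
    """Result of fitting the arm model to a marker frame."""

    joint_vector: JointVector
    residual: float            # RMS marker-to-model distance, metres
    degenerate: bool = False   # marker geometry was singular for the chain
    underdetermined: bool = False  # pronation unobservable (no wrist trackers)

    @property
    def q(self) -> np.ndarray:
        return self.joint_vector.angles


def _wrist_geometry(markers: MarkerFrame):
    """Wrist centre and (optional) radius->ulna lateral chord."""
    if all(m in markers for m in WRIST_MARKERS):
        rad = 0.5 * (markers["wrist_radius_1"] + markers["wrist_radius_2"])
        uln = 0.5 * (markers["wrist_ulna_1"] + markers["wrist_ulna_2"])
        return 0.5 * (rad + uln), rad - uln
    if "wrist" in markers:
        return markers["wrist"], None
    raise MarkerError(
        "need either the four ulna/radius wrist trackers or a 'wrist' marker")


def _closed_form_ik(skeleton: ArmSkeleton, p_E, p_W, p_P, lateral) -> Tuple[np.ndarray, bool]:
    """Sequential geometric IK.  Returns (q, degenerate_flag)."""
    L1, L2, L3 = skeleton.lengths
    p_S = skeleton.shoulder_position
    q = skeleton.rest_posture.copy()
    degenerate = False

    u = p_S - p_E
    v = p_W - p_E
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return q, True
    cosg = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    q4 = np.pi - np.arccos(cosg)
    q[3] = q4
    if abs(np.sin(q4)) < 1e-6:
        degenerate = True  # straight elbow: humeral rotation unobservable

    e_loc = np.array([0.0, 0.0, -L1])
    w_loc = e_loc + np.array([-L2 * np.sin(q4), 0.0, -L2 * np.cos(q4)])
    world = np.vstack([p_E - p_S, p_W - p_S])
    local = np.vstack([e_loc, w_loc])
    nw = np.linalg.norm(world, axis=1, keepdims=True)
    nl = np.linalg.norm(local, axis=1, keepdims=True)
    if np.any(nw < 1e-9) or degenerate:
        return q, True
    R_sh_rot, _ = Rotation.align_vectors(world / nw, local / nl)
    try:
        q[0], q[1], q[2] = R_sh_rot.as_euler("XZY")
    except Exception:  # pragma: no cover - gimbal edge
        degenerate = True
    R_sh = R_sh_rot.as_matrix()
    R4 = R_sh @ _rot_batch(q4, "y")

    if lateral is not None and np.linalg.norm(lateral) > 1e-9:
        d = R4.T @ lateral
        q[4] = np.arctan2(d[1], d[0])

    R5 = R4 @ _rot_batch(q[4], "z")
    h = R5.T @ (p_P - p_W)
    nh = np.linalg.norm(h)
    if nh < 1e-9:
        return q, True
    h = h / nh
    q[6] = np.arcsin(np.clip(h[1], -1.0, 1.0))
    if abs(h[0]) + abs(h[2]) > 1e-9:
        q[5] = np.arctan2(-h[0], -h[2])
    return q, degenerate


def ik_arm(skeleton: ArmSkeleton, markers: MarkerFrame,
           regularization: float = 1e-5) -> ArmFit:
    """Fit the 7-DoF arm to marker positions (point-to-point mapping).

    A closed-form geometric solution initializes a bounded least-squares
    refinement over the anthropomorphic limits.  The residual vector holds
    marker misfit (metres) plus ``regularization``-weighted deviation from
    the rest posture, which pins the otherwise-flat directions and makes
    the solution unique.  Geometrically inconsistent markers still return a
    solution, flagged by a large residual; a missing marker raises
    :class:`~bimanip.skeleton.MarkerError` naming it.
    """
    markers.require(ARM_IK_MARKERS)
    p_S = markers["shoulder"]
    p_E = markers["elbow"]
    p_P = markers["hand_center"]
    p_W, lateral = _wrist_geometry(markers)
    underdetermined = lateral is None

    skel = ArmSkeleton(
        side=skeleton.side, link_lengths=dict(skeleton.link_lengths),
        joint_limits=skeleton.joint_limits.copy(),
        rest_posture=skeleton.rest_posture.copy(), shoulder_position=p_S)

    q0, degenerate = _closed_form_ik(skel, p_E, p_W, p_P, lateral)
    lo, hi = skel.joint_limits[:, 0], skel.joint_limits[:, 1]
    q0 = np.clip(q0, lo + 1e-9, hi - 1e-9)

    if lateral is not None:
        targets = [("elbow", markers["elbow"])] + \
            [(m, markers[m]) for m in WRIST_MARKERS] + [("hand_center", p_P)]
    else:
        targets = [("elbow", markers["elbow"]), ("wrist", p_W), ("hand_center", p_P)]

    w, s = WRIST_MARKER_OFFSET, WRIST_MARKER_SPACING
    offsets = {
        "wrist_radius_1": np.array([w, 0.0, -s / 2]),
        "wrist_radius_2": np.array([w, 0.0, s / 2]),
        "wrist_ulna_1": np.array([-w, 0.0, -s / 2]),
        "wrist_ulna_2": np.array([-w, 0.0, s / 2]),
    }
    n_marker_res = 3 * len(targets)
    rest = skel.rest_posture

    def residual(q):
        fk = _fk_arm_batch(skel, q)
        out = np.empty(n_marker_res + ARM_DOF)
        i = 0
        for name, obs in targets:
            if name == "elbow":
                model = fk["p_elbow"]
            elif name == "wrist":
                model = fk["p_wrist"]
            elif name == "hand_center":
                model = fk["p_palm"]
            else:
                model = fk["p_wrist"] + fk["R5"] @ offsets[name]
            out[i:i + 3] = model - obs
            i += 3
        out[i:] = regularization * (q - rest)
        return out

    sol = least_squares(residual, q0, bounds=(lo, hi), method="trf",
                        ftol=1e-14, xtol=1e-14, gtol=1e-14)
    marker_res = sol.fun[:n_marker_res].reshape(-1, 3)
    rms = float(np.sqrt(np.mean(np.sum(marker_res ** 2, axis=1))))
    return ArmFit(skel.joint_vector(sol.x), residual=rms,
                  degenerate=degenerate, underdetermined=underdetermined)


# ---------------------------------------------------------------------------
# hand model
# ---------------------------------------------------------------------------

def _finger_marker_names(finger: str) -> Tuple[str, ...]:
    if finger == "thumb":
        return ("thumb_cmc", "thumb_mcp", "thumb_ip", "thumb_tip")
    return (f"{finger}_mcp", f"{finger}_pip", f"{finger}_dip", f"{finger}_tip")


def hand_marker_local(skeleton: HandSkeleton, q: np.ndarray) -> Dict[str, np.ndarray]:
    """Hand-frame marker positions for a 20-DoF joint configuration.

    The hand frame is the arm's end-effector frame: x radial, y palmar
    normal, z proximal (digits extend along -z); positive flexion curls
    toward +y.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (HAND_DOF,):
        raise SkeletonError(f"hand FK expects 20 angles, got {q.shape}")
    out: Dict[str, np.ndarray] = {"hand_center": np.zeros(3)}
    for fi, finger in enumerate(FINGERS):
        a, b, c, d = q[fi * 4:(fi + 1) * 4]
        lengths = skeleton.phalanx_lengths[finger]
        base = skeleton.finger_bases[finger]
        Ra = _rot_batch(a, "y")
        flex = np.cumsum([b, c, d])
        names = _finger_marker_names(finger)
        out[names[0]] = base.copy()
        p = base.copy()
        for k in range(3):
            v = Ra @ _rot_batch(flex[k], "x") @ (-_EZ)
            p = p + lengths[k] * v
            out[names[k + 1]] = p
    return out


def hand_marker_frame(skeleton: HandSkeleton, q: np.ndarray,
                      frame: RigidFrame) -> MarkerFrame:
    """World-frame hand markers given the hand base pose ``frame``."""
    local = hand_marker_local(skeleton, q)
    return MarkerFrame({k: frame.rotation @ v + frame.translation
                        for k, v in local.items()})


@dataclass
class HandFit:
    """Joint-to-joint hand fit: 20 angles + clip / missing flags."""

    angles: np.ndarray              # NaN for joints of missing fingers
    clipped: np.ndarray             # boolean, True where clipped to a limit
    missing_fingers: Tuple[str, ...]
    chain_id: str

    @property
    def joint_vector(self) -> JointVector:
        if self.missing_fingers:
            raise SkeletonError(
                f"fingers missing from marker set: {self.missing_fingers}")
        return JointVector(self.chain_id, self.angles)


def _palm_basis(markers: MarkerFrame) -> Tuple[np.ndarray, np.ndarray]:
    """(origin, 3x3 basis [x lateral, y normal, z proximal]) from markers."""
    c = markers["hand_center"]
    wrist_mid, _ = _wrist_geometry(markers)
    z = wrist_mid - c
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise SkeletonError("degenerate palm geometry: wrist coincides with centre")
    z = z / nz
    lat = markers["index_mcp"] - markers["little_mcp"]
    lat = lat - (lat @ z) * z
    nl = np.linalg.norm(lat)
    if nl < 1e-9:
        raise SkeletonError("degenerate palm geometry: knuckle line along forearm")
    x = lat / nl
    y = np.cross(z, x)
    return c, np.column_stack([x, y, z])


def hand_joint_angles(skeleton: HandSkeleton, markers: MarkerFrame) -> HandFit:
    """Per-joint angles computed directly from adjacent marker triplets.

    Angles are clipped to the anthropomorphic limits with a flag; a finger
    whose markers are missing is reported absent rather than raising.
    """
    markers.require(("hand_center", "index_mcp", "little_mcp"))
    origin, B = _palm_basis(markers)
    angles = np.full(HAND_DOF, np.nan)
    clipped = np.zeros(HAND_DOF, dtype=bool)
    missing = []
    for fi, finger in enumerate(FINGERS):
        names = _finger_marker_names(finger)
        if any(n not in markers for n in names):
            missing.append(finger)
            continue
        pts = np.array([B.T @ (markers[n] - origin) for n in names])
        v = np.diff(pts, axis=0)
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms < 1e-9):
            missing.append(finger)
            continue
        v = v / norms[:, None]
        a = np.arctan2(-v[0, 0], -v[0, 2])
        b = np.arcsin(np.clip(v[0, 1], -1.0, 1.0))
        lat = np.array([np.cos(a), 0.0, -np.sin(a)])
        c = np.arctan2(np.cross(v[0], v[1]) @ lat, v[0] @ v[1])
        d = np.arctan2(np.cross(v[1], v[2]) @ lat, v[1] @ v[2])
        angles[fi * 4:(fi + 1) * 4] = (a, b, c, d)
    raw = angles.copy()
    lo, hi = skeleton.joint_limits[:, 0], skeleton.joint_limits[:, 1]
    with np.errstate(invalid="ignore"):
        angles = np.clip(angles, lo, hi)
        clipped = np.abs(raw - angles) > 1e-12
    return HandFit(angles, clipped, tuple(missing), skeleton.chain_id)


# ---------------------------------------------------------------------------
# hand-object Jacobian
# ---------------------------------------------------------------------------

def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def _finger_joint_frames(skeleton: HandSkeleton, q: np.ndarray, finger: str):
    """Axes and pivots (hand frame) for one digit's 4 joints."""
    fi = FINGERS.index(finger)
    a, b, c, d = q[fi * 4:(fi + 1) * 4]
    base = skeleton.finger_bases[finger]
    lengths = skeleton.phalanx_lengths[finger]
    Ra = _rot_batch(a, "y")
    lat = Ra @ _EX
    flex = np.cumsum([b, c, d])
    pts = [base]
    for k in range(3):
        v = Ra @ _rot_batch(flex[k], "x") @ (-_EZ)
        pts.append(pts[-1] + lengths[k] * v)
    axes = [_EY, lat, lat, lat]
    pivots = [base, base, pts[1], pts[2]]
    return axes, pivots, pts


def contact_point_jacobian(skeleton: HandSkeleton, q: np.ndarray,
                           contact: Contact) -> np.ndarray:
    """6x20 spatial Jacobian of a contact point, hand frame."""
    q = np.asarray(q, dtype=float)
    axes, pivots, _ = _finger_joint_frames(skeleton, q, contact.finger)
    J = np.zeros((6, HAND_DOF))
    fi = FINGERS.index(contact.finger)
    active = 2 + contact.phalanx  # base 2 DoF + one flexion per distal phalanx
    for j in range(min(active, N_JOINTS_PER_FINGER)):
        col = fi * 4 + j
        J[:3, col] = np.cross(axes[j], contact.position - pivots[j])
        J[3:, col] = axes[j]
    return J


def stacked_contact_jacobian(skeleton: HandSkeleton, q: np.ndarray,
                             contacts: ContactSet) -> np.ndarray:
    """Soft-contact transmission Jacobian, (4*Nc) x 20.

    Per contact: 3 translational rows + 1 angular row about the contact
    normal (the soft-finger wrench basis).
    """
    rows = []
    for c in contacts:
        Jc = contact_point_jacobian(skeleton, q, c)
        rows.append(Jc[:3])
        rows.append((c.normal @ Jc[3:])[None, :])
    return np.vstack(rows)


def grasp_map(contacts: ContactSet, tool: RigidFrame) -> np.ndarray:
    """6 x (4*Nc) grasp map: contact wrench coords -> tool-origin wrench."""
    cols = []
    o = tool.translation
    for c in contacts:
        G = np.zeros((6, 4))
        G[:3, :3] = np.eye(3)
        G[3:, :3] = _skew(c.position - o)
        G[3:, 3] = c.normal
        cols.append(G)
    return np.hstack(cols)


def hand_object_jacobian(skeleton: HandSkeleton, q: JointVector | np.ndarray,
                         contacts: ContactSet, tool: RigidFrame) -> np.ndarray:
    """Hand-object Jacobian H (6x20) such that tau = H^T f.

    ``f`` is the wrench applied by the hand at the tool origin (hand-frame
    axes).  H composes the stacked soft-contact Jacobians with the
    pseudoinverse of the grasp map (minimum-norm contact force
    distribution), so the torque identity tau = H^T f holds by
    construction for any wrench in the grasp's range.
    """
    qa = q.angles if isinstance(q, JointVector) else np.asarray(q, dtype=float)
    if qa.shape != (HAND_DOF,):
        raise SkeletonError(f"expected 20 hand angles, got {qa.shape}")
    if len(contacts) == 0:  # ContactSet forbids this, but guard anyway
        raise SkeletonError("empty contact set")
    Jh = stacked_contact_jacobian(skeleton, qa, contacts)
    G = grasp_map(contacts, tool)
    return np.linalg.pinv(G).T @ Jh


def joint_torques(H: np.ndarray, f: np.ndarray) -> np.ndarray:
    """tau = H^T f for an object wrench (6,) or pure force (3,)."""
    f = np.asarray(f, dtype=float)
    if f.shape == (3,):
        f = np.concatenate([f, np.zeros(3)])
    return H.T @ f
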