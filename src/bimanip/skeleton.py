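"""Skeleton models of the human arm and hand.

The arm is a 7-DoF serial chain (shoulder 3, elbow 1, wrist 3) with three
rigid links (upper arm, forearm, hand link).  The hand is a 20-DoF model:
the thumb has 4 DoF (CMC ab/adduction + flexion, MCP flexion, IP/DIP
flexion) and each of the four fingers has 4 DoF (MCP ab/adduction +
flexion, PIP flexion, DIP flexion).

Kinematic convention (declared, right-handed, Z up, metres, radians):

=====  ==============================  =====================================
index  degree of freedom               axis at the zero posture
=====  ==============================  =====================================
0      shoulder ab/adduction           world X
1      shoulder circumduction          local Z (upper-arm long axis)
2      shoulder extension/flexion      local Y
3      elbow extension/flexion         local Y
4      forearm pronation/supination    local Z (forearm long axis)
5      wrist extension/flexion         local Y
6      wrist ulnar/radial deviation    local X
=====  ==============================  =====================================

At the all-zero posture every link hangs along world -Z from the shoulder.
Joint limits are stored in radians; configuration files use degrees for
readability and are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import yaml

FINGERS = ("thumb", "index", "middle", "ring", "little")
N_FINGERS = 5
N_JOINTS_PER_FINGER = 4
ARM_DOF = 7
HAND_DOF = N_FINGERS * N_JOINTS_PER_FINGER

ARM_DOF_NAMES = (
    "shoulder_abduction",
    "shoulder_circumduction",
    "shoulder_flexion",
    "elbow_flexion",
    "forearm_pronation",
    "wrist_flexion",
    "wrist_deviation",
)

#: default anthropomorphic motion ranges, degrees (lower, upper), and rest
#: angles.  Editable through structured config files; these are package
#: defaults, not empirical claims.
DEFAULT_ARM_LIMITS_DEG: Tuple[Tuple[float, float], ...] = (
    (-45.0, 120.0),   # shoulder ab/adduction
    (-60.0, 60.0),    # shoulder circumduction
    (-60.0, 90.0),    # shoulder extension/flexion
    (10.0, 150.0),    # elbow flexion (kept off full extension: desk work)
    (-80.0, 80.0),    # forearm pronation/supination
    (-70.0, 80.0),    # wrist extension/flexion
    (-30.0, 20.0),    # ulnar/radial deviation
)
DEFAULT_ARM_REST_DEG: Tuple[float, ...] = (15.0, 10.0, 25.0, 80.0, 10.0, -10.0, 0.0)

#: default link lengths, metres (upper arm, forearm, hand link)
DEFAULT_LINK_LENGTHS = {"upper_arm": 0.30, "forearm": 0.26, "hand": 0.08}

#: lateral offset of the ulna/radius wrist trackers from the wrist centre (m)
WRIST_MARKER_OFFSET = 0.025
#: proximal offset (along the forearm) between the two trackers on each bone
WRIST_MARKER_SPACING = 0.015


class SkeletonError(ValueError):
    """Invalid skeleton definition or joint configuration."""


class MarkerError(KeyError):
    """A required marker is missing from a MarkerFrame."""


@dataclass(frozen=True)
class JointVector:
    """An ordered set of joint angles for one kinematic chain.

    ``chain_id`` identifies the chain (e.g. ``"arm_right"``); ``angles``
    has the chain's DoF count and is radians throughout.
    """

    chain_id: str
    angles: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if not np.all(np.isfinite(a)):
            raise SkeletonError(f"non-finite joint angle in chain {self.chain_id!r}")
        object.__setattr__(self, "angles", a)

    def __len__(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class RigidFrame:
    """A rigid transform: 3x3 rotation (orthonormal, det +1) + translation (m)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise SkeletonError("RigidFrame needs a 3x3 rotation and a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise SkeletonError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidFrame":
        return cls(np.eye(3), np.zeros(3))

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class MarkerFrame:
    """Named 3-D tracker positions in the world frame (metres)."""

    positions: Dict[str, np.ndarray]
    timestamp: float = 0.0

    def __post_init__(self):
        clean = {}
        for name, p in self.positions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise SkeletonError(f"marker {name!r} is not a finite 3-vector")
            clean[name] = p
        self.positions = clean

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.positions[name]
        except KeyError:
            raise MarkerError(f"required marker {name!r} is missing") from None

    def __contains__(self, name: str) -> bool:
        return name in self.positions

    def require(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.positions]
        if missing:
            raise MarkerError(f"required markers missing: {missing}")


def _validate_limits(limits: np.ndarray, rest: np.ndarray, what: str) -> np.ndarray:
    limits = np.asarray(limits, dtype=float)
    rest = np.asarray(rest, dtype=float)
    if np.any(limits[:, 0] >= limits[:, 1]):
        raise SkeletonError(f"{what}: every lower limit must be < upper limit")
    if np.any(rest < limits[:, 0]) or np.any(rest > limits[:, 1]):
        raise SkeletonError(f"{what}: rest posture must lie within joint limits")
    ranges = np.minimum(rest - limits[:, 0], limits[:, 1] - rest)
    if np.any(ranges <= 0):
        raise SkeletonError(f"{what}: rest posture on a joint limit (zero range)")
    return ranges


@dataclass
class ArmSkeleton:
    """7-DoF arm: link lengths, joint limits, rest posture.

    ``joint_ranges`` (Q_i) is the distance from the rest angle to the nearer
    joint limit, used to normalize joint excursions in the comfort measure.
    """

    side: str = "right"
    link_lengths: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINK_LENGTHS))
    joint_limits: np.ndarray = field(
        default_factory=lambda: np.deg2rad(np.array(DEFAULT_ARM_LIMITS_DEG)))
    rest_posture: np.ndarray = field(
        default_factory=lambda: np.deg2rad(np.array(DEFAULT_ARM_REST_DEG)))
    shoulder_position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise SkeletonError("side must be 'left' or 'right'")
        for key in ("upper_arm", "forearm", "hand"):
            if self.link_lengths.get(key, 0.0) <= 0.0:
                raise SkeletonError(f"link length {key!r} must be positive")
        self.joint_limits = np.asarray(self.joint_limits, dtype=float)
        self.rest_posture = np.asarray(self.rest_posture, dtype=float)
        self.shoulder_position = np.asarray(self.shoulder_position, dtype=float)
        if self.joint_limits.shape != (ARM_DOF, 2) or self.rest_posture.shape != (ARM_DOF,):
            raise SkeletonError("arm skeleton must have exactly 7 DoF")
        self.joint_ranges = _validate_limits(
            self.joint_limits, self.rest_posture, f"arm_{self.side}")

    @property
    def chain_id(self) -> str:
        return f"arm_{self.side}"

    @property
    def lengths(self) -> Tuple[float, float, float]:
        return (self.link_lengths["upper_arm"],
                self.link_lengths["forearm"],
                self.link_lengths["hand"])

    def check_limits(self, q: np.ndarray) -> np.ndarray:
        """Boolean mask of joints violating their limits."""
        q = np.asarray(q, dtype=float)
        return (q < self.joint_limits[:, 0] - 1e-12) | (q > self.joint_limits[:, 1] + 1e-12)

    def assert_within_limits(self, q: np.ndarray) -> None:
        bad = np.flatnonzero(self.check_limits(q))
        if bad.size:
            j = int(bad[0])
            raise SkeletonError(
                f"joint {j} ({ARM_DOF_NAMES[j]}) = {float(np.asarray(q)[j]):.4f} rad "
                f"outside limits {tuple(self.joint_limits[j])}")

    def clip(self, q: np.ndarray) -> np.ndarray:
        return np.clip(q, self.joint_limits[:, 0], self.joint_limits[:, 1])

    def joint_vector(self, q: np.ndarray) -> JointVector:
        return JointVector(self.chain_id, np.asarray(q, dtype=float))


# ---------------------------------------------------------------------------
# hand model defaults
# ---------------------------------------------------------------------------

#: per-finger joint names, in chain order (2 DoF at the base joint, then two
#: interphalangeal flexions).  The thumb base joint is the CMC.
HAND_JOINT_NAMES: Tuple[str, ...] = tuple(
    f"{f}_{j}" for f in FINGERS
    for j in (("cmc_abduction", "cmc_flexion", "mcp_flexion", "ip_flexion")
              if f == "thumb" else
              ("mcp_abduction", "mcp_flexion", "pip_flexion", "dip_flexion"))
)

_FINGER_LIMITS_DEG = {
    "thumb": ((-30.0, 30.0), (-30.0, 60.0), (-10.0, 80.0), (-15.0, 85.0)),
    "other": ((-25.0, 25.0), (-20.0, 90.0), (0.0, 110.0), (-10.0, 80.0)),
}
_FINGER_REST_DEG = {
    "thumb": (10.0, 15.0, 20.0, 15.0),
    "other": (0.0, 20.0, 25.0, 10.0),
}

#: phalanx lengths (m): thumb (metacarpal, proximal, distal);
#: fingers (proximal, middle, distal)
DEFAULT_PHALANX_LENGTHS: Dict[str, Tuple[float, float, float]] = {
    "thumb": (0.046, 0.032, 0.025),
    "index": (0.040, 0.025, 0.019),
    "middle": (0.045, 0.028, 0.020),
    "ring": (0.042, 0.027, 0.019),
    "little": (0.033, 0.020, 0.017),
}

#: finger base (knuckle) positions in the hand frame (m): x lateral
#: (radial +), y palm-normal, z proximal (fingers extend along -z)
DEFAULT_FINGER_BASES: Dict[str, np.ndarray] = {
    "thumb": np.array([0.045, -0.005, 0.005]),
    "index": np.array([0.025, 0.0, -0.035]),
    "middle": np.array([0.008, 0.0, -0.040]),
    "ring": np.array([-0.012, 0.0, -0.038]),
    "little": np.array([-0.030, 0.0, -0.032]),
}


def _default_hand_limits() -> np.ndarray:
    rows = []
    for f in FINGERS:
        key = "thumb" if f == "thumb" else "other"
        rows.extend(_FINGER_LIMITS_DEG[key])
    return np.deg2rad(np.array(rows))


def _default_hand_rest() -> np.ndarray:
    rows = []
    for f in FINGERS:
        key = "thumb" if f == "thumb" else "other"
        rows.extend(_FINGER_REST_DEG[key])
    return np.deg2rad(np.array(rows))


@dataclass
class HandSkeleton:
    """20-DoF hand: five 4-DoF digit chains anchored on a rigid palm."""

    side: str = "right"
    phalanx_lengths: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHALANX_LENGTHS))
    joint_limits: np.ndarray = field(default_factory=_default_hand_limits)
    rest_posture: np.ndarray = field(default_factory=_default_hand_rest)
    finger_bases: Dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_FINGER_BASES.items()})

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise SkeletonError("side must be 'left' or 'right'")
        self.joint_limits = np.asarray(self.joint_limits, dtype=float)
        self.rest_posture = np.asarray(self.rest_posture, dtype=float)
        if self.joint_limits.shape != (HAND_DOF, 2) or self.rest_posture.shape != (HAND_DOF,):
            raise SkeletonError("hand skeleton must have exactly 20 DoF")
        for f in FINGERS:
            if f not in self.phalanx_lengths or len(self.phalanx_lengths[f]) != 3:
                raise SkeletonError(f"finger {f!r} needs 3 phalanx lengths")
            if min(self.phalanx_lengths[f]) <= 0:
                raise SkeletonError(f"finger {f!r} phalanx lengths must be positive")
        self.joint_ranges = _validate_limits(
            self.joint_limits, self.rest_posture, f"hand_{self.side}")

    @property
    def chain_id(self) -> str:
        return f"hand_{self.side}"

    def finger_slice(self, finger: str) -> slice:
        i = FINGERS.index(finger)
        return slice(i * N_JOINTS_PER_FINGER, (i + 1) * N_JOINTS_PER_FINGER)

    def clip(self, q: np.ndarray) -> np.ndarray:
        return np.clip(q, self.joint_limits[:, 0], self.joint_limits[:, 1])

    def check_limits(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return (q < self.joint_limits[:, 0] - 1e-12) | (q > self.joint_limits[:, 1] + 1e-12)

    def joint_vector(self, q: np.ndarray) -> JointVector:
        return JointVector(self.chain_id, np.asarray(q, dtype=float))


@dataclass(frozen=True)
class Contact:
    """A single soft contact on a phalanx surface (hand frame, metres)."""

    finger: str
    phalanx: int           # 0-based phalanx index along the digit chain
    position: np.ndarray   # contact point, hand frame
    normal: np.ndarray     # unit contact normal, hand frame

    def __post_init__(self):
        if self.finger not in FINGERS:
            raise SkeletonError(f"unknown finger {self.finger!r}")
        if self.phalanx not in (0, 1, 2):
            raise SkeletonError("phalanx index must be 0, 1 or 2")
        p = np.asarray(self.position, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise SkeletonError("contact normal must be nonzero")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "normal", n / nn)


@dataclass
class ContactSet:
    """Soft-finger contacts between the hand and a held tool."""

    contacts: List[Contact]
    model: str = "soft"

    def __post_init__(self):
        if not self.contacts:
            raise SkeletonError("ContactSet must contain at least one contact")

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)


# ---------------------------------------------------------------------------
# config round trip
# ---------------------------------------------------------------------------

def arm_to_config(skel: ArmSkeleton) -> dict:
    return {
        "side": skel.side,
        "link_lengths_m": dict(skel.link_lengths),
        "joint_limits_deg": np.rad2deg(skel.joint_limits).tolist(),
        "rest_posture_deg": np.rad2deg(skel.rest_posture).tolist(),
        "shoulder_position_m": skel.shoulder_position.tolist(),
    }


def arm_from_config(cfg: Mapping) -> ArmSkeleton:
    return ArmSkeleton(
        side=cfg.get("side", "right"),
        link_lengths=dict(cfg["link_lengths_m"]),
        joint_limits=np.deg2rad(np.array(cfg["joint_limits_deg"], dtype=float)),
        rest_posture=np.deg2rad(np.array(cfg["rest_posture_deg"], dtype=float)),
        shoulder_position=np.array(cfg.get("shoulder_position_m", [0, 0, 0]), dtype=float),
    )


def load_arm_skeleton(path) -> ArmSkeleton:
    """Load an arm definition from a YAML config (limits in degrees)."""
    with open(path) as fh:
        return arm_from_config(yaml.safe_load(fh))


def save_arm_skeleton(skel: ArmSkeleton, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(arm_to_config(skel), fh, sort_keys=False)
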