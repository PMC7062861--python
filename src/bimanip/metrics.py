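"""Kinematic goodness measures: manipulability, force transmission, comfort.

Three scalar metrics grade a limb configuration:

* manipulability ``omega = sqrt(det(J J^T))`` — the volume of the velocity
  ellipsoid, i.e. distance from kinematic singularity;
* force-transmission ratio ``alpha = (u^T (J J^T) u)^(-1/2)`` — the radius
  of the force ellipsoid ``f^T (J J^T) f = 1`` along a task direction u;
* comfort ``eps = 1 - (1/N_J) sum_j beta'_j ((q_j - q_j^r)/Q_j)^2`` — unity
  at the rest posture, decreasing as joints approach their limits, with
  optional per-joint weights beta' (normalized to sum 1).

The same kernels serve the arm (J = arm Jacobian) and the hand
(J = hand-object Jacobian H).  By default the arm uses the translational
3x7 Jacobian block, since the task demand u is a pure force direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .skeleton import ArmSkeleton, HandSkeleton, JointVector, SkeletonError


class MetricError(ValueError):
    pass


class UnboundedTransmissionError(MetricError):
    """u lies in the null space of J^T: no torque resists force along u."""


@dataclass(frozen=True)
class MetricValue:
    """A named metric value, with the direction of interest for alpha."""

    name: str
    value: float
    chain_id: str = ""
    direction: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.name not in ("omega", "alpha", "epsilon"):
            raise MetricError(f"unknown metric {self.name!r}")
        if self.direction is not None:
            u = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(u) - 1.0) > 1e-9:
                raise MetricError("direction of interest must be unit norm")
            object.__setattr__(self, "direction", u)


@dataclass(frozen=True)
class BetaWeights:
    """Per-joint comfort weights beta', normalized across joints to sum 1."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise MetricError("beta weights must be non-negative")
        s = w.sum()
        if abs(s - 1.0) > 1e-9:
            raise MetricError("beta weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, n: int) -> "BetaWeights":
        return cls(np.full(n, 1.0 / n))

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "BetaWeights":
        raw = np.asarray(raw, dtype=float)
        s = raw.sum()
        if s <= 0:
            raise MetricError("cannot normalize all-zero beta weights")
        return cls(raw / s)


def manipulability(J: np.ndarray) -> float:
    """omega = sqrt(det(J J^T)), the product of J's singular values."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] > J.shape[1]:
        raise MetricError(
            f"J must have at least as many columns as rows, got {J.shape}")
    gram = J @ J.T
    det = np.linalg.det(gram)
    return float(np.sqrt(max(det, 0.0)))


def manipulability_batch(J: np.ndarray) -> np.ndarray:
    """Vectorized omega over leading batch axes of J (..., m, n)."""
    gram = J @ np.swapaxes(J, -1, -2)
    return np.sqrt(np.maximum(np.linalg.det(gram), 0.0))


def force_transmission(J: np.ndarray, u: np.ndarray) -> float:
    """alpha = (u^T (J J^T) u)^(-1/2) along the unit direction u."""
    J = np.asarray(J, dtype=float)
    u = np.asarray(u, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise MetricError("direction of interest u must be unit norm")
    if u.shape[0] != J.shape[0]:
        raise MetricError(
            f"dimension mismatch: u has {u.shape[0]} rows, J has {J.shape[0]}")
    quad = float(u @ (J @ (J.T @ u)))
    if quad <= 1e-300:
        raise UnboundedTransmissionError(
            "u is orthogonal to the row space of J: unbounded transmission")
    return float(quad ** -0.5)


def force_transmission_batch(J: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized alpha; u may broadcast over the batch, (..., m)."""
    Ju = np.swapaxes(J, -1, -2) @ u[..., None]
    quad = np.sum(Ju[..., 0] ** 2, axis=-1)
    return np.where(quad > 0, quad, np.nan) ** -0.5


def _comfort(q, rest, ranges, beta_w, n_joints) -> float:
    dev = (np.asarray(q, dtype=float) - rest) / ranges
    return 1.0 - float(np.sum(beta_w * dev ** 2)) / n_joints


def comfort_arm(q: JointVector | np.ndarray, skeleton: ArmSkeleton,
                beta: Optional[BetaWeights] = None) -> float:
    """Arm comfort.  ``beta=None`` weights every joint equally (beta_j = 1,
    the unweighted form); supplying :class:`BetaWeights` (beta' summing to 1)
    reproduces the variance-weighted form, still averaged over N_J."""
    qa = q.angles if isinstance(q, JointVector) else np.asarray(q, dtype=float)
    if np.any(skeleton.joint_ranges <= 0):
        raise MetricError("zero joint range: comfort undefined")
    n = qa.size
    w = np.ones(n) if beta is None else skeleton_beta(beta, n)
    return _comfort(qa, skeleton.rest_posture, skeleton.joint_ranges, w, n)


def skeleton_beta(beta: BetaWeights, n: int) -> np.ndarray:
    w = beta.weights
    if w.size != n:
        raise MetricError(f"beta has {w.size} weights for a {n}-joint chain")
    return w


def comfort_arm_batch(Q: np.ndarray, skeleton: ArmSkeleton,
                      beta: Optional[BetaWeights] = None) -> np.ndarray:
    n = skeleton.rest_posture.size
    w = np.ones(n) if beta is None else skeleton_beta(beta, n)
    dev = (np.asarray(Q, dtype=float) - skeleton.rest_posture) / skeleton.joint_ranges
    return 1.0 - np.sum(w * dev ** 2, axis=-1) / n


def comfort_hand(q: JointVector | np.ndarray, skeleton: HandSkeleton) -> float:
    """Hand comfort: mean squared normalized deviation over all 20 joints."""
    qa = q.angles if isinstance(q, JointVector) else np.asarray(q, dtype=float)
    if np.any(skeleton.joint_ranges <= 0):
        raise MetricError("zero joint range: comfort undefined")
    n = qa.size
    return _comfort(qa, skeleton.rest_posture, skeleton.joint_ranges,
                    np.ones(n), n)


def hand_metrics(H: np.ndarray, u: np.ndarray) -> Tuple[float, float]:
    """(omega_h, alpha_h) for a hand-object Jacobian H.

    ``u`` must already be expressed in the hand's coordinate frame (project
    with the arm end-effector rotation first); a 3-vector u selects the
    translational block of a 6-row H.
    """
    H = np.asarray(H, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape[0] == 3 and H.shape[0] == 6:
        Ht = H[:3]
    else:
        Ht = H
    return manipulability(Ht), force_transmission(Ht, u)


def project_direction(u_world: np.ndarray, frame_rotation: np.ndarray) -> np.ndarray:
    """Express a world-frame direction in a limb frame (R^T u), re-normalized."""
    u = np.asarray(frame_rotation, dtype=float).T @ np.asarray(u_world, dtype=float)
    n = np.linalg.norm(u)
    if n < 1e-12:
        raise MetricError("zero direction cannot be projected")
    return u / n
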