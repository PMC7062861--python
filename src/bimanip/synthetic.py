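"""Synthetic study generator with planted ground truth.

Every stage of the analysis pipeline is testable without recorded human
data: a synthetic subject carries known cost weights, and its posture is
*generated by solving the lower-level problem at those weights*, so the
inverse optimization has a recoverable planted truth.  Markers are the
forward-kinematic tracker positions plus isotropic Gaussian noise
(default 1.63 mm RMS per marker, the reconstruction error of a
multi-camera marking pipeline), and force recordings are anisotropic
Gaussian clouds with a dominant direction, mimicking the 70 Hz
force-sensor signal during a swipe.

Group templates mirror the watchmaking study design: ten novices and five
experts, with the expert group putting markedly more weight on dominant-arm
comfort (0.465 vs 0.258) and less on task compatibility.

Determinism: all randomness flows through ``numpy.random.Generator``
(PCG64) seeded from a single ``SeedSequence``; the same seed reproduces a
cohort bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .inverse_opt import (
    DEFAULT_SELECTED_JOINTS,
    ArmStateSpace,
    CostBasis,
    WeightVector,
    lower_level_solve,
    normalization_constants,
)
from .kinematics import arm_marker_frame, fk_arm, hand_marker_frame
from .skeleton import (
    ArmSkeleton,
    HandSkeleton,
    MarkerFrame,
    RigidFrame,
)
from .task_demand import ForceSegment, TaskDemand, decompose_demand

SIDES = ("left", "right")

#: group mean weights (manipulability, task compatibility, comfort)
NOVICE_WEIGHTS = {"left": (0.3338, 0.3573, 0.3089),
                  "right": (0.3931, 0.3486, 0.2583)}
EXPERT_WEIGHTS = {"left": (0.3931, 0.3486, 0.2583),
                  "right": (0.3941, 0.1406, 0.4653)}

#: dominant task-demand force direction (task frame), pressing down on the
#: watch face with a horizontal push component
DEFAULT_FORCE_DIRECTION = np.array([-0.09, 0.19, -0.97])

_SHOULDERS = {"right": np.array([0.18, 0.55, 0.35]),
              "left": np.array([-0.18, 0.55, 0.35])}


class SyntheticError(ValueError):
    pass


@dataclass
class CohortProfile:
    """Generating conditions for one subject group."""

    label: str
    mean_weights: Dict[str, Tuple[float, float, float]]
    weight_dispersion: float = 0.10        # logistic-normal sigma
    marker_noise: float = 1.63e-3          # RMS marker displacement, m
    force_direction: np.ndarray = field(
        default_factory=lambda: DEFAULT_FORCE_DIRECTION.copy())
    force_axis_ratio: float = 3.0          # major : minor axis of the cloud
    force_sigma_major: float = 0.30        # N, spread along the major axis
    force_mean_magnitude: float = 1.0      # N
    force_direction_jitter_deg: float = 2.0
    segments_per_subject: int = 12
    samples_per_segment: int = 210         # ~3 s at 70 Hz
    success_probability: float = 0.575

    def __post_init__(self):
        if self.weight_dispersion < 0:
            raise SyntheticError("weight dispersion must be >= 0")
        if self.force_axis_ratio < 1:
            raise SyntheticError("force axis ratio must be >= 1")
        for side in SIDES:
            w = np.asarray(self.mean_weights[side], dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
                raise SyntheticError(f"mean weights for {side} must be a simplex point")
        d = np.asarray(self.force_direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise SyntheticError("force direction must be nonzero")
        self.force_direction = d / n


def novice_profile(**overrides) -> CohortProfile:
    return CohortProfile(label="novice", mean_weights=dict(NOVICE_WEIGHTS),
                         success_probability=0.575, segments_per_subject=12,
                         **overrides)


def expert_profile(**overrides) -> CohortProfile:
    return CohortProfile(label="expert", mean_weights=dict(EXPERT_WEIGHTS),
                         success_probability=0.835, segments_per_subject=11,
                         **overrides)


@dataclass
class SyntheticSubject:
    """One generated subject with its planted ground truth."""

    subject_id: str
    group: str
    seed: int
    arms: Dict[str, ArmSkeleton]
    hands: Dict[str, HandSkeleton]
    true_weights: Dict[str, WeightVector]
    true_state: Dict[str, np.ndarray]      # lower-level optimum per side
    true_q: Dict[str, np.ndarray]          # full 7-joint posture per side
    theta: float                           # watch rotation (right-arm state)
    hand_pose: Dict[str, np.ndarray]
    markers: Dict[str, MarkerFrame]        # noisy tracker positions
    force_segments: List[ForceSegment]
    bases: Dict[str, CostBasis]            # normalized cost bases used
    demand: TaskDemand
    watch_pose: RigidFrame = field(default_factory=RigidFrame.identity)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _draw_weights(mean: np.ndarray, dispersion: float,
                  rng: np.random.Generator) -> WeightVector:
    """Logistic-normal perturbation of a simplex mean (stays interior)."""
    z = np.log(np.maximum(mean, 1e-9)) + dispersion * rng.standard_normal(3)
    return WeightVector(_softmax(z))


def _jitter_direction(d: np.ndarray, sigma_deg: float,
                      rng: np.random.Generator) -> np.ndarray:
    if sigma_deg <= 0:
        return d
    perturb = np.deg2rad(sigma_deg) * rng.standard_normal(3)
    v = d + np.cross(perturb, d)
    return v / np.linalg.norm(v)


def _force_cloud(profile: CohortProfile, direction: np.ndarray, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Anisotropic Gaussian force samples with the given principal axis."""
    # orthonormal frame with `direction` first
    a = direction
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    b = np.cross(a, helper)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    R = np.column_stack([a, b, c])
    sig = np.array([profile.force_sigma_major,
                    profile.force_sigma_major / profile.force_axis_ratio,
                    profile.force_sigma_major / profile.force_axis_ratio])
    local = rng.standard_normal((n, 3)) * sig
    mean = profile.force_mean_magnitude * direction
    return mean + local @ R.T


def generate_subject(profile: CohortProfile, seed: int,
                     subject_id: str = "S01",
                     selected_joints: Sequence[int] = DEFAULT_SELECTED_JOINTS,
                     sides: Sequence[str] = SIDES,
                     ) -> SyntheticSubject:
    """Generate one subject: skeletons, planted weights, posture, markers,
    force segments.

    The posture is the lower-level optimum of the subject's own true
    weights (re-solving at those weights reproduces it within solver
    tolerance); markers carry isotropic Gaussian noise whose per-marker
    RMS displacement equals ``profile.marker_noise``.
    """
    ss = np.random.SeedSequence(seed)
    (k_anthro, k_weights, k_kappa, k_lower, k_hand,
     k_noise, k_force) = ss.spawn(7)
    rng = np.random.default_rng(k_anthro)

    scale = rng.uniform(0.9, 1.1, size=3)  # shared across sides: symmetry
    lengths = {"upper_arm": 0.30 * scale[0], "forearm": 0.26 * scale[1],
               "hand": 0.08 * scale[2]}

    demand = decompose_demand(profile.force_direction)
    u_for = {"left": demand.u_left, "right": demand.u_right}

    rng_w = np.random.default_rng(k_weights)
    rng_lower = np.random.default_rng(k_lower)
    kappa_seeds = k_kappa.spawn(2)

    arms, hands, bases = {}, {}, {}
    true_weights, true_state, true_q, hand_pose, markers = {}, {}, {}, {}, {}
    theta = 0.0
    rng_hand = np.random.default_rng(k_hand)
    rng_noise = np.random.default_rng(k_noise)

    for si, side in enumerate(SIDES):
        if side not in sides:
            continue
        skel = ArmSkeleton(side=side, link_lengths=dict(lengths),
                           shoulder_position=_SHOULDERS[side].copy())
        arms[side] = skel
        hands[side] = HandSkeleton(side=side)
        w = _draw_weights(np.asarray(profile.mean_weights[side], dtype=float),
                          profile.weight_dispersion, rng_w)
        true_weights[side] = w

        space = ArmStateSpace(skel, selected=tuple(selected_joints),
                              include_theta=(side == "right"))
        basis = CostBasis(space, u_task=u_for[side])
        kappa_seed = int(kappa_seeds[si].generate_state(1)[0] % (2**31 - 1))
        basis.kappa = normalization_constants(basis, seed=kappa_seed)
        bases[side] = basis

        lower_seed = int(rng_lower.integers(2**31 - 1))
        low = lower_level_solve(w, basis, seed=lower_seed)
        true_state[side] = low.x
        Q, th = space.expand(low.x[None, :])
        true_q[side] = Q[0]
        if side == "right":
            theta = float(th[0])

        # hand pose: rest plus a small per-joint perturbation
        hskel = hands[side]
        span = np.deg2rad(5.0)
        pose = hskel.clip(hskel.rest_posture +
                          rng_hand.uniform(-span, span, hskel.rest_posture.size))
        hand_pose[side] = pose

        frame, _ = fk_arm(skel, true_q[side])
        arm_mf = arm_marker_frame(skel, true_q[side])
        hand_mf = hand_marker_frame(hskel, pose, frame)
        merged = dict(arm_mf.positions)
        for name, p in hand_mf.positions.items():
            if name not in merged:  # hand_center already present from the arm
                merged[name] = p
        sigma = profile.marker_noise / np.sqrt(3.0)
        noisy = {k: v + rng_noise.normal(0.0, sigma, 3)
                 for k, v in merged.items()}
        markers[side] = MarkerFrame(noisy)

    rng_force = np.random.default_rng(k_force)
    segments: List[ForceSegment] = []
    for s in range(profile.segments_per_subject):
        d = _jitter_direction(profile.force_direction,
                              profile.force_direction_jitter_deg, rng_force)
        n = profile.samples_per_segment
        forces = _force_cloud(profile, d, n, rng_force)
        t = np.arange(n) / 70.0
        success = bool(rng_force.random() < profile.success_probability)
        segments.append(ForceSegment(timestamps=t, forces=forces,
                                     success=success, subject=subject_id,
                                     segment_id=f"{subject_id}_seg{s:02d}"))

    c, s = np.cos(theta), np.sin(theta)
    watch_pose = RigidFrame(
        np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]),
        np.array([0.0, 0.30, 0.02]))

    return SyntheticSubject(
        subject_id=subject_id, group=profile.label, seed=seed,
        arms=arms, hands=hands, true_weights=true_weights,
        true_state=true_state, true_q=true_q, theta=theta,
        hand_pose=hand_pose, markers=markers, force_segments=segments,
        bases=bases, demand=demand, watch_pose=watch_pose)


def generate_cohort(novice: Optional[CohortProfile] = None,
                    expert: Optional[CohortProfile] = None,
                    n_novice: int = 10, n_expert: int = 5,
                    seed: int = 0,
                    selected_joints: Sequence[int] = DEFAULT_SELECTED_JOINTS,
                    sides: Sequence[str] = SIDES,
                    ) -> List[SyntheticSubject]:
    """Generate the two-group study cohort (defaults: 10 novices, 5 experts)."""
    novice = novice if novice is not None else novice_profile()
    expert = expert if expert is not None else expert_profile()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_novice + n_expert)
    cohort = []
    for i in range(n_novice):
        sid = f"N{i + 1:02d}"
        s = int(subject_seeds[i].generate_state(1)[0] % (2**31 - 1))
        cohort.append(generate_subject(novice, s, subject_id=sid,
                                       selected_joints=selected_joints,
                                       sides=sides))
    for j in range(n_expert):
        sid = f"E{n_novice + j + 1:02d}"
        s = int(subject_seeds[n_novice + j].generate_state(1)[0] % (2**31 - 1))
        cohort.append(generate_subject(expert, s, subject_id=sid,
                                       selected_joints=selected_joints,
                                       sides=sides))
    return cohort
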