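"""Study orchestration: IK fits, metrics, task demands, inverse
optimization, alignment geometry, and group statistics.

``run_study`` chains the full analysis over a cohort of subjects
(synthetic or loaded from marker/force files): markers -> constrained IK
-> kinematic metrics -> force-ellipsoid task demands (from the expert
group's successful segments) -> per-subject, per-arm bi-level inverse
optimization -> one-way ANOVA group contrasts.  All tables are plain
pandas DataFrames; angles are degrees in reports and radians internally.
p-values are reported descriptively, without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import json
import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import __version__ as _pkg_version
from .inverse_opt import (
    DEFAULT_SELECTED_JOINTS,
    ArmStateSpace,
    CostBasis,
    beta_from_cohort,
    normalization_constants,
    upper_level_solve,
)
from .kinematics import arm_jacobian, fk_arm, hand_joint_angles, ik_arm
from .metrics import (
    MetricError,
    comfort_arm,
    comfort_hand,
    force_transmission,
    manipulability,
)
from .skeleton import RigidFrame
from .synthetic import SIDES, SyntheticSubject
from .task_demand import (
    Ellipsoid,
    TaskDemand,
    TaskDemandError,
    demand_from_segments,
    major_axis,
)


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# alignment geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentAngles:
    """Watch rotation and force-ellipsoid alignment angles, degrees.

    theta: signed watch rotation about Z (positive anticlockwise),
    in (-180, 180].
    vartheta: signed angle of the ellipsoid major axis, projected onto the
    horizontal plane, from the +X world axis.
    delta: included angle between the task direction u and the projected
    major axis, folded into [0, 90] by the axis' sign symmetry.
    """

    theta: float
    vartheta: float
    delta: float

    def __post_init__(self):
        if not (-180.0 < self.theta <= 180.0):
            raise PipelineError("theta must be in (-180, 180] degrees")
        if not (0.0 <= self.delta <= 90.0):
            raise PipelineError("delta must be in [0, 90] degrees")


def alignment_angles(watch_pose: RigidFrame, ellipsoid: Ellipsoid,
                     u: np.ndarray) -> AlignmentAngles:
    """The three coordination angles of a limb/watch configuration."""
    R = watch_pose.rotation
    theta = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    if theta <= -180.0:
        theta += 360.0

    axis = major_axis(ellipsoid)
    h = axis[:2]
    nh = np.linalg.norm(h)
    if nh < 1e-6:
        raise PipelineError(
            "major axis is (near-)vertical: projected angles undefined")
    vartheta = float(np.degrees(np.arctan2(h[1], h[0])))

    u = np.asarray(u, dtype=float)
    u2 = u[:2]
    nu = np.linalg.norm(u2)
    if nu < 1e-12:
        raise PipelineError("u has no horizontal component: delta undefined")
    cosd = abs(float(u2 @ h)) / (nu * nh)
    delta = float(np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0))))
    return AlignmentAngles(theta=theta, vartheta=vartheta, delta=delta)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA contrast of a scalar metric across groups."""

    metric: str
    group_labels: Tuple[str, ...]
    group_means: Tuple[float, ...]
    group_sds: Tuple[float, ...]
    f_statistic: float
    dof: Tuple[int, int]
    p_value: float
    degenerate: bool = False

    def __post_init__(self):
        if self.f_statistic < 0:
            raise PipelineError("F statistic must be non-negative")


def one_way_anova(groups: Sequence[Sequence[float]],
                  labels: Optional[Sequence[str]] = None,
                  metric: str = "") -> GroupComparison:
    """Classical between/within variance decomposition.

    Zero variance everywhere yields F = 0 by convention (flagged
    ``degenerate``) instead of a NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise PipelineError("need >= 2 groups with >= 2 values each")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    k = len(arrays)
    N = sum(a.size for a in arrays)
    dof = (k - 1, N - k)
    means = tuple(float(a.mean()) for a in arrays)
    sds = tuple(float(a.std(ddof=1)) for a in arrays)
    concat = np.concatenate(arrays)
    if np.ptp(concat) < 1e-300:
        return GroupComparison(metric, tuple(labels), means, sds,
                               0.0, dof, 1.0, degenerate=True)
    F, p = sp_stats.f_oneway(*arrays)
    if not np.isfinite(F):  # zero within-group variance
        return GroupComparison(metric, tuple(labels), means, sds,
                               0.0, dof, 1.0, degenerate=True)
    return GroupComparison(metric, tuple(labels), means, sds,
                           float(F), dof, float(p))


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {"metric": c.metric, "F": c.f_statistic,
               "dof_between": c.dof[0], "dof_within": c.dof[1],
               "p": c.p_value, "degenerate": c.degenerate}
        for lab, m, s in zip(c.group_labels, c.group_means, c.group_sds):
            row[f"mean_{lab}"] = m
            row[f"sd_{lab}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study configuration and report bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Numeric protocol of the analysis run."""

    seed: int = 0
    sides: Tuple[str, ...] = ("left", "right")
    selected_joints: Tuple[int, ...] = DEFAULT_SELECTED_JOINTS
    restarts: int = 5
    upper_budget: int = 500
    lower_maxiter: int = 60
    beta_mode: str = "uniform"       # "uniform" | "cohort"
    mvee_tolerance: float = 1e-4     # axis extraction needs direction only
    significance: float = 0.05


@dataclass
class StudyReport:
    """All output tables of one study run plus provenance."""

    subjects: pd.DataFrame
    metrics: pd.DataFrame
    weights: pd.DataFrame
    alignment: pd.DataFrame
    comparisons: pd.DataFrame
    demand: TaskDemand
    provenance: Dict

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("subjects", "metrics", "weights", "alignment", "comparisons"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        prov = dict(self.provenance)
        prov["task_demand"] = {
            "f_star": self.demand.f_star.tolist(),
            "u_left": self.demand.u_left.tolist(),
            "u_right": self.demand.u_right.tolist(),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))


def _arm_force_ellipsoid(J3: np.ndarray) -> Ellipsoid:
    """The arm's force ellipsoid f^T (J J^T) f = 1 as an Ellipsoid object."""
    A = J3 @ J3.T
    return Ellipsoid(center=np.zeros(3), shape=0.5 * (A + A.T))


def run_study(cohort: Sequence[SyntheticSubject],
              config: Optional[StudyConfig] = None) -> StudyReport:
    """Run the full analysis chain over a cohort and collect the report."""
    cfg = config if config is not None else StudyConfig()
    if not cohort:
        raise PipelineError("empty cohort")
    ss = np.random.SeedSequence(cfg.seed)
    subject_seeds = ss.spawn(len(cohort))
    errors: List[Dict] = []

    # --- task demand from the expert group's successful segments ---------
    expert_segments = [seg for s in cohort if s.group == "expert"
                       for seg in s.force_segments]
    if not any(seg.success for seg in expert_segments):
        expert_segments = [seg for s in cohort for seg in s.force_segments]
    demand = demand_from_segments(expert_segments, tolerance=cfg.mvee_tolerance)
    u_task = {"left": demand.u_left, "right": demand.u_right}

    # --- IK fits ----------------------------------------------------------
    fits: Dict[Tuple[str, str], np.ndarray] = {}
    subj_rows = []
    for subj in cohort:
        n_seg = len(subj.force_segments)
        n_succ = sum(seg.success for seg in subj.force_segments)
        subj_rows.append({
            "subject": subj.subject_id, "group": subj.group,
            "n_segments": n_seg, "n_success": n_succ,
            "success_rate": n_succ / n_seg if n_seg else np.nan,
        })
        for side in cfg.sides:
            fit = ik_arm(subj.arms[side], subj.markers[side])
            fits[(subj.subject_id, side)] = fit.q
    subjects_df = pd.DataFrame(subj_rows)

    beta = None
    if cfg.beta_mode == "cohort":
        betas = {}
        for side in cfg.sides:
            Q = np.array([fits[(s.subject_id, side)] for s in cohort])
            betas[side] = beta_from_cohort(Q)
        beta = betas
    elif cfg.beta_mode != "uniform":
        raise PipelineError(f"unknown beta_mode {cfg.beta_mode!r}")

    # --- metrics + alignment ---------------------------------------------
    metric_rows, align_rows = [], []
    for subj in cohort:
        for side in cfg.sides:
            q = fits[(subj.subject_id, side)]
            skel = subj.arms[side]
            J3 = arm_jacobian(skel, q, check_limits=False)[:3]
            b = None if beta is None else beta[side]
            try:
                alpha = force_transmission(J3, u_task[side])
            except MetricError:
                alpha = np.nan
            hand_fit = hand_joint_angles(subj.hands[side], subj.markers[side])
            eps_h = (np.nan if hand_fit.missing_fingers
                     else comfort_hand(hand_fit.angles, subj.hands[side]))
            metric_rows.append({
                "subject": subj.subject_id, "group": subj.group, "side": side,
                "chain": f"arm_{side}",
                "omega": manipulability(J3),
                "alpha": alpha,
                "epsilon": comfort_arm(q, skel, b),
                "epsilon_hand": eps_h,
            })
            try:
                ang = alignment_angles(
                    subj.watch_pose, _arm_force_ellipsoid(J3), u_task[side])
                align_rows.append({
                    "subject": subj.subject_id, "group": subj.group,
                    "side": side, "theta_deg": ang.theta,
                    "vartheta_deg": ang.vartheta, "delta_deg": ang.delta})
            except (PipelineError, TaskDemandError) as e:
                errors.append({"stage": "alignment", "subject": subj.subject_id,
                               "side": side, "error": str(e)})
    metrics_df = pd.DataFrame(metric_rows)
    align_df = pd.DataFrame(align_rows)

    # --- inverse optimization --------------------------------------------
    weight_rows = []
    for subj, sseed in zip(cohort, subject_seeds):
        side_seeds = sseed.spawn(len(cfg.sides))
        for side, side_seed in zip(cfg.sides, side_seeds):
            skel = subj.arms[side]
            q_obs = fits[(subj.subject_id, side)]
            space = ArmStateSpace(skel, selected=cfg.selected_joints,
                                  defaults=skel.clip(q_obs),
                                  include_theta=(side == "right"))
            basis = CostBasis(space, u_task=u_task[side],
                              beta=None if beta is None else beta[side])
            seeds = side_seed.spawn(3)
            kseed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
            useed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))
            basis.kappa = normalization_constants(basis, seed=kseed)
            x_obs = q_obs[list(cfg.selected_joints)]
            if side == "right":
                R = subj.watch_pose.rotation
                theta_obs = float(np.arctan2(R[1, 0], R[0, 0]))
                x_obs = np.append(x_obs, ((theta_obs + np.pi / 2) % np.pi)
                                  - np.pi / 2)
            x_obs = np.clip(x_obs, space.bounds[:, 0], space.bounds[:, 1])
            try:
                res = upper_level_solve(
                    x_obs, basis, restarts=cfg.restarts,
                    budget=cfg.upper_budget, seed=useed,
                    lower_maxiter=cfg.lower_maxiter)
            except Exception as e:  # keep the partial report
                errors.append({"stage": "iop", "subject": subj.subject_id,
                               "side": side, "error": str(e)})
                continue
            w = res.weights.values
            row = {"subject": subj.subject_id, "group": subj.group,
                   "side": side, "w_manipulability": w[0],
                   "w_task_compatibility": w[1], "w_comfort": w[2],
                   "phi": res.phi, "restarts": cfg.restarts}
            if subj.true_weights is not None and side in subj.true_weights:
                tw = subj.true_weights[side].values
                row.update({"w_true_manipulability": tw[0],
                            "w_true_task_compatibility": tw[1],
                            "w_true_comfort": tw[2]})
            weight_rows.append(row)
    weights_df = pd.DataFrame(weight_rows)

    # --- group contrasts --------------------------------------------------
    comparisons: List[GroupComparison] = []
    group_labels = tuple(sorted({s.group for s in cohort}))
    if len(group_labels) >= 2:
        def contrast(df, col, name):
            try:
                groups = [df.loc[df.group == g, col].dropna().to_numpy()
                          for g in group_labels]
                if all(len(g) >= 2 for g in groups):
                    comparisons.append(one_way_anova(groups, group_labels, name))
            except PipelineError as e:
                errors.append({"stage": "anova", "metric": name, "error": str(e)})

        for side in cfg.sides:
            mdf = metrics_df[metrics_df.side == side]
            for col in ("omega", "alpha", "epsilon", "epsilon_hand"):
                contrast(mdf, col, f"{col}_{side}")
            wdf = weights_df[weights_df.side == side] if len(weights_df) else weights_df
            for col in ("w_manipulability", "w_task_compatibility", "w_comfort"):
                if len(wdf):
                    contrast(wdf, col, f"{col}_{side}")
            adf = align_df[align_df.side == side] if len(align_df) else align_df
            if len(adf):
                contrast(adf, "delta_deg", f"delta_{side}")
        if len(align_df):
            theta_df = align_df[align_df.side == cfg.sides[-1]]
            contrast(theta_df, "theta_deg", "theta")
        contrast(subjects_df.assign(side="both"), "success_rate", "success_rate")
    comp_df = comparison_frame(comparisons) if comparisons else pd.DataFrame()

    provenance = {
        "package_version": _pkg_version,
        "seed": cfg.seed,
        "restarts": cfg.restarts,
        "upper_budget": cfg.upper_budget,
        "lower_maxiter": cfg.lower_maxiter,
        "beta_mode": cfg.beta_mode,
        "selected_joints": list(cfg.selected_joints),
        "sides": list(cfg.sides),
        "n_subjects": len(cohort),
        "errors": errors,
    }
    return StudyReport(subjects=subjects_df, metrics=metrics_df,
                       weights=weights_df, alignment=align_df,
                       comparisons=comp_df, demand=demand,
                       provenance=provenance)
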