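"""Bi-level inverse optimization of the composite kinematic criterion.

The central nervous system is modelled as maximizing a weighted sum of
normalized kinematic metrics over a box of postural state variables
(selected arm joints, plus the watch rotation theta for the dominant
arm).  The inverse problem recovers the weights:

* lower level: ``x(w) = argmax_x  sum_i w_i kappa_i Psi_i(x)`` over the
  box, where ``Psi = (manipulability, task compatibility, comfort)`` and
  ``kappa_i = 1 / max_x Psi_i(x)`` normalizes each metric into [0, 1];
* upper level: ``min_w Phi(x(w), x*)`` over the weight simplex
  ``{w_i in [0, 1], sum w_i = 1}``, with ``Phi`` the mean squared error of
  the state variables (radians) against the observed posture ``x*``.

Both levels use a bounded, seeded global derivative-free solver
(differential evolution); the solve protocol (restarts, upper-level
evaluation budget, e^-5 lower-level stopping) is configurable, with
defaults of 5 restarts and 500 upper-level trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import differential_evolution

from .kinematics import _arm_axes_batch, _fk_arm_batch
from .metrics import (
    BetaWeights,
    MetricError,
    comfort_arm_batch,
    force_transmission_batch,
    manipulability_batch,
)
from .skeleton import ARM_DOF, ARM_DOF_NAMES, ArmSkeleton

METRIC_NAMES = ("manipulability", "task_compatibility", "comfort")
N_METRICS = 3

#: sensitive joints used as lower-level state variables by default:
#: shoulder circumduction, elbow flexion, forearm pronation, wrist flexion
DEFAULT_SELECTED_JOINTS = (1, 3, 4, 5)

LOWER_STOP = math.exp(-5)  # population-spread stopping threshold


class InverseOptError(ValueError):
    pass


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of v onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    n = v.size
    mu = np.sort(v)[::-1]
    cssv = np.cumsum(mu) - 1.0
    rho = np.flatnonzero(mu - cssv / (np.arange(n) + 1) > 0)[-1]
    theta = cssv[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass(frozen=True)
class WeightVector:
    """Simplex weights over (manipulability, task compatibility, comfort)."""

    values: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.values, dtype=float)
        if w.shape != (N_METRICS,):
            raise InverseOptError(f"expected {N_METRICS} weights, got {w.shape}")
        if np.any(w < -1e-12) or np.any(w > 1.0 + 1e-12):
            raise InverseOptError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InverseOptError("weights must sum to 1")
        object.__setattr__(self, "values", np.clip(w, 0.0, 1.0))

    @classmethod
    def normalized(cls, raw: Sequence[float]) -> "WeightVector":
        raw = np.asarray(raw, dtype=float)
        s = raw.sum()
        if s <= 0 or np.any(raw < 0):
            raise InverseOptError("raw weights must be non-negative, sum > 0")
        return cls(raw / s)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(METRIC_NAMES, self.values.tolist()))


@dataclass
class ArmStateSpace:
    """The lower-level search box: selected joints (+ optional theta).

    Unselected joints are pinned to ``defaults`` (typically the IK fit of
    the observed posture).  ``include_theta`` adds the watch rotation,
    bounded in [-pi, pi], which re-orients the task-demand direction.
    """

    skeleton: ArmSkeleton
    selected: Tuple[int, ...] = DEFAULT_SELECTED_JOINTS
    defaults: Optional[np.ndarray] = None
    include_theta: bool = False

    def __post_init__(self):
        self.selected = tuple(int(i) for i in self.selected)
        if any(i < 0 or i >= ARM_DOF for i in self.selected):
            raise InverseOptError("selected joint index out of range")
        if len(set(self.selected)) != len(self.selected):
            raise InverseOptError("duplicate selected joints")
        if self.defaults is None:
            self.defaults = self.skeleton.rest_posture.copy()
        self.defaults = np.asarray(self.defaults, dtype=float)
        if self.defaults.shape != (ARM_DOF,):
            raise InverseOptError("defaults must give all 7 joint angles")
        self.skeleton.assert_within_limits(self.defaults)

    @property
    def n_state(self) -> int:
        return len(self.selected) + (1 if self.include_theta else 0)

    @property
    def bounds(self) -> np.ndarray:
        rows = [self.skeleton.joint_limits[i] for i in self.selected]
        if self.include_theta:
            rows.append((-np.pi, np.pi))
        return np.array(rows, dtype=float)

    @property
    def names(self) -> Tuple[str, ...]:
        out = [ARM_DOF_NAMES[i] for i in self.selected]
        if self.include_theta:
            out.append("watch_rotation")
        return tuple(out)

    def expand(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(S, n_state) -> full joint angles (S, 7) and theta (S,)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        S = X.shape[0]
        Q = np.tile(self.defaults, (S, 1))
        Q[:, list(self.selected)] = X[:, :len(self.selected)]
        theta = X[:, -1] if self.include_theta else np.zeros(S)
        return Q, theta

    def canonicalize(self, x: np.ndarray) -> np.ndarray:
        """Fold theta into [-pi/2, pi/2).

        The force-transmission ratio is quadratic in the demand direction,
        so u and -u are equivalent and theta is identifiable only mod pi;
        folding picks a unique representative of each optimum.
        """
        x = np.asarray(x, dtype=float).copy()
        if self.include_theta:
            x[-1] = ((x[-1] + np.pi / 2) % np.pi) - np.pi / 2
        return x

    def contains(self, x: np.ndarray, tol: float = 1e-9) -> bool:
        b = self.bounds
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= b[:, 0] - tol) and np.all(x <= b[:, 1] + tol))


def _translational_jacobian_batch(fk) -> np.ndarray:
    """Linear-velocity Jacobian rows only, (..., 3, 7), from cached FK."""
    axes = _arm_axes_batch(fk)
    batch = fk["p_palm"].shape[:-1]
    pivots = np.empty(batch + (7, 3))
    pivots[..., 0:3, :] = fk["p_shoulder"][..., None, :]
    pivots[..., 3, :] = fk["p_elbow"]
    pivots[..., 4:7, :] = fk["p_wrist"][..., None, :]
    arm = fk["p_palm"][..., None, :] - pivots
    return np.swapaxes(np.cross(axes, arm), -1, -2)


def _rotz_batch(theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


@dataclass
class CostBasis:
    """The metric evaluators Psi_i with their normalization constants kappa.

    ``u_task`` is the task-demanded force direction in the task (watch)
    frame; for the dominant arm it is re-oriented by the watch rotation,
    ``u_world = Rz(theta) u_task``.
    """

    space: ArmStateSpace
    u_task: np.ndarray
    beta: Optional[BetaWeights] = None
    kappa: Optional[np.ndarray] = None

    def __post_init__(self):
        u = np.asarray(self.u_task, dtype=float)
        n = np.linalg.norm(u)
        if n < 1e-12:
            raise InverseOptError("u_task must be a nonzero direction")
        self.u_task = u / n
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)
            if self.kappa.shape != (N_METRICS,) or np.any(self.kappa <= 0):
                raise InverseOptError("kappa must be 3 positive constants")

    def raw_metrics(self, X: np.ndarray) -> np.ndarray:
        """(S, n_state) -> (S, 3) raw metric values (pre-kappa)."""
        Q, theta = self.space.expand(X)
        skel = self.space.skeleton
        fk = _fk_arm_batch(skel, Q)
        J3 = _translational_jacobian_batch(fk)
        omega = manipulability_batch(J3)
        if self.space.include_theta:
            u_world = (_rotz_batch(theta) @ self.u_task)
        else:
            u_world = np.broadcast_to(self.u_task, theta.shape + (3,))
        alpha = force_transmission_batch(J3, u_world)
        eps = comfort_arm_batch(Q, skel, self.beta)
        return np.column_stack([omega, alpha, eps])

    def composite(self, X: np.ndarray, weights: WeightVector) -> np.ndarray:
        """Normalized composite sum_i w_i kappa_i Psi_i, batched."""
        if self.kappa is None:
            raise InverseOptError("normalization constants not set; call "
                                  "normalization_constants first")
        raw = self.raw_metrics(X)
        raw = np.nan_to_num(raw, nan=-np.inf)
        return raw @ (weights.values * self.kappa)


def _polish_maximize(fun_batch, x0: np.ndarray, bounds: np.ndarray,
                     fd_step: float = 1e-6):
    """Bounded L-BFGS-B refinement with a batched central-difference gradient."""
    from scipy.optimize import minimize

    lo, hi = bounds[:, 0], bounds[:, 1]
    d = x0.size

    def fun(x):
        return -float(fun_batch(np.asarray(x, dtype=float)[None, :])[0])

    def jac(x):
        x = np.asarray(x, dtype=float)
        steps = np.minimum(fd_step, (hi - lo) * 1e-3)
        Xp = np.clip(np.repeat(x[None, :], d, axis=0) + np.diag(steps), lo, hi)
        Xm = np.clip(np.repeat(x[None, :], d, axis=0) - np.diag(steps), lo, hi)
        vals = np.asarray(fun_batch(np.vstack([Xp, Xm])), dtype=float)
        denom = np.maximum(np.diagonal(Xp) - np.diagonal(Xm), 1e-300)
        return -(vals[:d] - vals[d:]) / denom

    res = minimize(fun, x0, jac=jac, method="L-BFGS-B",
                   bounds=list(zip(lo, hi)), options={"maxiter": 60})
    return res.x, -float(res.fun)


def _de_maximize(fun_batch: Callable[[np.ndarray], np.ndarray],
                 bounds: np.ndarray, seed, maxiter: int = 60,
                 popsize: int = 8, atol: float = LOWER_STOP,
                 polish: bool = True, polish_topk: int = 1):
    """Seeded vectorized differential evolution, maximizing fun_batch.

    ``polish_topk > 1`` refines that many of the best population members
    (guards against a multimodal landscape where the incumbent basin is
    not the global one).
    """

    def neg(x):
        # scipy hands (d, S) when vectorized
        X = np.atleast_2d(np.asarray(x, dtype=float).T)
        val = -np.asarray(fun_batch(X), dtype=float)
        return val if np.asarray(x).ndim == 2 else val[0]

    res = differential_evolution(
        neg, bounds=bounds, seed=seed, maxiter=maxiter, popsize=popsize,
        tol=0.0, atol=atol, init="sobol", polish=False, vectorized=True,
        updating="deferred")
    x, val = res.x, -float(res.fun)
    if polish:
        b = np.asarray(bounds, dtype=float)
        starts = [x]
        if polish_topk > 1:
            order = np.argsort(res.population_energies)[:polish_topk]
            starts.extend(res.population[i] for i in order)
        for x0 in starts:
            xp, vp = _polish_maximize(fun_batch, np.asarray(x0, dtype=float), b)
            if vp >= val:
                x, val = xp, vp
    return x, val, res


def normalization_constants(basis: CostBasis, seed: int = 0,
                            maxiter: int = 60) -> np.ndarray:
    """kappa_i = 1 / max_x Psi_i(x) over the state box.

    The maxima are found with the same bounded derivative-free solver used
    by the lower level, at a fixed budget; a metric with non-positive
    maximum is unusable and raises.
    """
    sub_seeds = np.random.SeedSequence(seed).spawn(N_METRICS)
    kappa = np.empty(N_METRICS)
    for i in range(N_METRICS):
        def one(X, i=i):
            v = basis.raw_metrics(X)[:, i]
            return np.nan_to_num(v, nan=-np.inf)
        rng = np.random.default_rng(sub_seeds[i])
        _, best, _ = _de_maximize(one, basis.space.bounds, rng,
                                  maxiter=maxiter, atol=1e-7,
                                  popsize=16, polish_topk=3)
        if not np.isfinite(best) or best <= 0:
            raise InverseOptError(
                f"metric {METRIC_NAMES[i]!r} has non-positive maximum "
                f"({best}) over the box: cannot normalize")
        kappa[i] = 1.0 / best
    return kappa


def with_normalization(basis: CostBasis, seed: int = 0) -> CostBasis:
    """Return a copy of ``basis`` with kappa computed."""
    return replace(basis, kappa=normalization_constants(basis, seed=seed))


@dataclass
class LowerLevelResult:
    x: np.ndarray
    objective: float
    n_evaluations: int
    n_iterations: int


def lower_level_solve(weights: WeightVector | Sequence[float], basis: CostBasis,
                      seed: int = 0, maxiter: int = 60,
                      popsize: int = 8) -> LowerLevelResult:
    """Maximize the normalized composite over the state box.

    Weights are renormalized on entry, so scaled copies of the same weight
    vector produce identical solutions.  Stops when the population spread
    of the objective falls below e^-5, then polishes with a bounded
    quasi-Newton step.
    """
    if not isinstance(weights, WeightVector):
        weights = WeightVector.normalized(np.asarray(weights, dtype=float))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x, val, res = _de_maximize(
        lambda X: basis.composite(X, weights), basis.space.bounds, rng,
        maxiter=maxiter, popsize=popsize)
    if not np.isfinite(val):
        raise InverseOptError("lower level failed: objective non-finite "
                              "everywhere it was evaluated")
    return LowerLevelResult(x=basis.space.canonicalize(np.asarray(x)),
                            objective=val,
                            n_evaluations=int(res.nfev), n_iterations=int(res.nit))


@dataclass
class RestartTrace:
    weights: np.ndarray
    phi: float
    n_upper_evaluations: int
    seed: int


@dataclass
class IOPResult:
    """Best recovered weights and the per-restart protocol trace."""

    weights: WeightVector
    phi: float
    restarts: List[RestartTrace]
    seed: int
    upper_budget: int
    lower_seed: int = 0  # the fixed lower-level seed used inside Phi

    @property
    def best_restart(self) -> int:
        return int(np.argmin([r.phi for r in self.restarts]))


def phi_joint_mse(x: np.ndarray, observed: np.ndarray,
                  space: Optional[ArmStateSpace] = None) -> float:
    """Upper-level distance: mean squared state-variable error (rad^2).

    When ``space`` includes theta, the theta error is the circular
    distance mod pi (the demand direction's sign ambiguity), so postures
    on either side of the fold boundary compare as close.
    """
    x = np.asarray(x, dtype=float)
    observed = np.asarray(observed, dtype=float)
    d = x - observed
    if space is not None and space.include_theta:
        d[-1] = ((d[-1] + np.pi / 2) % np.pi) - np.pi / 2
    return float(np.mean(d ** 2))


def upper_level_solve(observed: np.ndarray, basis: CostBasis,
                      restarts: int = 5, budget: int = 500,
                      seed: int = 0, lower_maxiter: int = 60,
                      lower_popsize: int = 8) -> IOPResult:
    """Recover the weight vector whose lower-level optimum matches ``observed``.

    Runs ``restarts`` independent seeded searches over the simplex (two
    free coordinates, Euclidean-projected, so the sum-to-one constraint is
    exact at every evaluation), each with about ``budget`` upper-level
    trials, and keeps the restart with the best Phi.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (basis.space.n_state,):
        raise InverseOptError(
            f"observed state must have {basis.space.n_state} entries")
    if not basis.space.contains(observed):
        raise InverseOptError("observed state lies outside the state bounds")
    if basis.kappa is None:
        raise InverseOptError("basis must be normalized (kappa set)")

    ss = np.random.SeedSequence(seed)
    lower_seed_root, *restart_seeds = ss.spawn(restarts + 1)
    # one fixed lower-level seed: Phi must be a deterministic function of w
    lower_seed = int(lower_seed_root.generate_state(1)[0] % (2**31 - 1))

    cache: Dict[Tuple[float, float, float], float] = {}

    def solve_lower(w: WeightVector) -> np.ndarray:
        return lower_level_solve(w, basis, seed=lower_seed,
                                 maxiter=lower_maxiter,
                                 popsize=lower_popsize).x

    def phi_of(z: np.ndarray) -> float:
        w = project_simplex(np.array([z[0], z[1], 1.0 - z[0] - z[1]]))
        key = tuple(np.round(w, 12))
        if key not in cache:
            if w.sum() <= 0:
                return np.inf
            wv = WeightVector.normalized(w)
            cache[key] = phi_joint_mse(solve_lower(wv), observed, basis.space)
        return cache[key]

    pop = 12  # individuals per generation in the 2-D simplex search
    refine_budget = max(15, budget // 4)
    maxiter = max(1, (budget - refine_budget) // pop - 1)
    traces: List[RestartTrace] = []
    for r, rseed in enumerate(restart_seeds):
        rint = int(rseed.generate_state(1)[0] % (2**31 - 1))
        res = differential_evolution(
            phi_of, bounds=[(0.0, 1.0), (0.0, 1.0)],
            seed=np.random.default_rng(rint), maxiter=maxiter,
            popsize=max(2, pop // 2), tol=0.0, atol=0.0, init="sobol",
            polish=False, updating="immediate")
        # local simplex refinement of the incumbent (budget-capped)
        from scipy.optimize import minimize
        nm = minimize(phi_of, res.x, method="Nelder-Mead",
                      options={"maxfev": refine_budget, "xatol": 1e-5,
                               "fatol": 1e-14})
        z = nm.x if nm.fun <= res.fun else res.x
        phi = float(min(nm.fun, res.fun))
        w = project_simplex(np.array([z[0], z[1], 1.0 - z[0] - z[1]]))
        traces.append(RestartTrace(weights=w, phi=phi,
                                   n_upper_evaluations=int(res.nfev + nm.nfev),
                                   seed=rint))
    best = min(traces, key=lambda t: t.phi)
    return IOPResult(weights=WeightVector.normalized(best.weights),
                     phi=best.phi, restarts=traces, seed=seed,
                     upper_budget=budget, lower_seed=lower_seed)


def beta_from_cohort(cohort_angles: np.ndarray) -> BetaWeights:
    """beta'_j: per-joint population standard deviation across subjects,
    normalized across joints to sum 1."""
    Q = np.asarray(cohort_angles, dtype=float)
    if Q.ndim != 2 or Q.shape[0] < 2:
        raise InverseOptError("need at least 2 subjects (rows)")
    raw = np.std(Q, axis=0, ddof=0)
    raw[raw < 1e-12 * max(1.0, float(np.abs(Q).max()))] = 0.0
    if raw.sum() <= 0:
        raise InverseOptError("all joints identical across subjects: "
                              "beta weights undefined")
    try:
        return BetaWeights.from_raw(raw)
    except MetricError as e:  # pragma: no cover
        raise InverseOptError(str(e))
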