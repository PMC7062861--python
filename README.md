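# bimanip

Kinematic coordination analysis for bimanual fine manipulation.

When both hands cooperate on a precision task — the motivating example
is watchmaking assembly, where the assistant hand presses a pegwood
vertically onto a watch face while the dominant hand pushes tweezers
horizontally — the upper limbs have far more degrees of freedom than the
task requires.  Optimal-control theory explains the consistent postures
people adopt by positing that the central nervous system (CNS) optimizes
a composite criterion.  `bimanip` implements that analysis end to end
and, crucially, the *inverse* problem: given an observed posture, infer
the weights the CNS assigned to each cost.

The package is aimed at motor-control researchers who want a tested,
seeded, fully synthetic-data-capable implementation of:

* **skeleton models** — a 7-DoF arm (shoulder 3, elbow 1, wrist 3) and a
  20-DoF hand, with forward kinematics, Jacobians, constrained
  marker-based inverse kinematics, and a soft-contact hand–object
  Jacobian `H` with `τ = Hᵀ f`;
* **dexterity metrics** — manipulability `ω = √det(J Jᵀ)`, the
  force-transmission ratio `α = (uᵀ J Jᵀ u)^(−1/2)` along a task
  direction `u`, and a comfort index
  `ε = 1 − (1/N_J) Σ β′_j ((q_j − q_j^r)/Q_j)²`;
* **task-demand extraction** — minimum-volume enclosing ellipsoids
  (Khachiyan) fitted to force recordings; the mean major axis `f*` is
  split into a vertical demand `u_L` for the assistant hand and a
  horizontal demand `u_R` for the dominant hand;
* **Sobol screening** — variance-based selection of the joints that
  actually move the metrics (5% sensitivity threshold);
* **bi-level inverse optimization** — lower level: maximize
  `Σ w_i κ_i Ψ_i(x)` over the joint box (+ watch rotation θ); upper
  level: find the simplex weights `w` whose lower-level optimum best
  matches the observed posture (joint-space mean squared error `Φ`),
  with a restartable, seeded, derivative-free solve protocol;
* **a synthetic cohort generator** — subjects with planted ground-truth
  weights whose postures are generated by the lower level itself, noisy
  markers (1.63 mm RMS), and anisotropic force clouds, so the whole
  pipeline is testable without any recorded data.

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

Generate one synthetic subject, refit its posture from the noisy
markers, extract the task demand from its force recordings, and recover
its cost weights:

```python
import numpy as np
from bimanip import (generate_subject, novice_profile, ik_arm, arm_jacobian,
                     manipulability, force_transmission, comfort_arm,
                     demand_from_segments, upper_level_solve)
from bimanip.inverse_opt import ArmStateSpace, CostBasis, normalization_constants

subj = generate_subject(novice_profile(), seed=42, subject_id="N01")
fit = ik_arm(subj.arms["right"], subj.markers["right"])
demand = demand_from_segments(subj.force_segments)
J3 = arm_jacobian(subj.arms["right"], fit.q, check_limits=False)[:3]

space = ArmStateSpace(subj.arms["right"],
                      defaults=subj.arms["right"].clip(fit.q),
                      include_theta=True)
basis = CostBasis(space, u_task=demand.u_right)
basis.kappa = normalization_constants(basis, seed=0)
x_obs = np.append(fit.q[list(space.selected)],
                  ((subj.theta + np.pi / 2) % np.pi) - np.pi / 2)
res = upper_level_solve(np.clip(x_obs, space.bounds[:, 0], space.bounds[:, 1]),
                        basis, restarts=2, budget=100, seed=0)
```

This prints (via the obvious `print` calls):

```
true right-arm weights: [0.369 0.416 0.215]
IK residual (m): 0.0019
f*: [-0.106  0.214 -0.971]  u_R: [-0.445  0.895  0.   ]
omega: 0.078  alpha: 4.333  epsilon: 0.787
recovered weights: [0.361 0.425 0.214]  Phi: 1.97e-04
```

Reading the numbers: the IK residual (1.9 mm) matches the configured
marker noise; the extracted dominant force direction `f*` points down
and slightly left-forward, so the assistant hand's demand is pure
vertical and the dominant hand's demand `u_R` is its horizontal
component; `ω`, `α`, `ε` grade the fitted posture (comfort 0.79 — close
to rest); and the inverse optimization recovers the subject's planted
weight vector to within 0.01 from noisy markers alone, with `Φ` the
residual joint-space mean squared error in rad².

A command-line surface wraps the same functionality:

```bash
bimanip simulate --seed 0 --n-novice 10 --n-expert 5 --out cohort/
bimanip fit-ellipsoid cohort/N01/N01_seg*.tsv
bimanip metrics --markers cohort/N01/markers_right.tsv
bimanip sensitivity --n-base 4096
bimanip recover --seed 1 --restarts 5 --budget 200
bimanip ioc --seed 0 --out report/
```

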