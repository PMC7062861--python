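# Methods

`bimanip` models how the central nervous system (CNS) selects upper-limb
postures in a bimanual fine-manipulation setting (the motivating task is
watchmaking-style assembly: the assistant hand presses a pegwood
vertically onto a small workpiece while the dominant hand pushes a pair
of tweezers horizontally).  The package implements the full analysis
chain — skeleton fitting, dexterity metrics, task-demand extraction,
state-variable screening, and a bi-level inverse optimization of cost
weights — and a synthetic-study generator that plants a known ground
truth so that every stage is testable without recorded human data.

## Models

### Arm skeleton (7 DoF)

Three rigid links (upper arm, forearm, hand link) and seven revolute
DoF: shoulder ab/adduction, circumduction, extension/flexion; elbow
flexion; forearm pronation/supination; wrist extension/flexion;
ulnar/radial deviation.  The chain convention (axis order and zero
posture) is declared in `bimanip.skeleton`: at the zero posture all
links hang along world −Z and the rotation sequence is
`Rx(q1) Rz(q2) Ry(q3) · Ry(q4) · Rz(q5) Ry(q6) Rx(q7)`.  The
end-effector frame sits at the palm centre and doubles as the hand
model's base frame.  Link lengths, joint limits and rest postures are
package defaults (editable via YAML config, degrees in files, radians in
memory); they are plausible anthropomorphic values, not measurements.
The default elbow range starts at 10° flexion: desk work never reaches
full extension, and a straight elbow makes humeral rotation unobservable
from point markers.

Inverse kinematics is a point-to-point mapping: a closed-form geometric
cascade (elbow angle from the triangle inequality; shoulder rotation by
aligning two body-frame vectors; pronation from the ulna/radius tracker
chord; wrist angles from the palm direction) initializes a bounded
least-squares refinement over the joint limits with a small
(1e-5-weighted) deviation-from-rest regularizer that makes the solution
unique.  With the four ulna/radius wrist trackers all seven DoF are
identifiable; with a single wrist point the rotation about the
wrist→palm axis is a null direction, and the fit is flagged
`underdetermined` (the regularizer then pins that direction at rest).

### Hand skeleton (20 DoF)

Five 4-DoF digit chains on a rigid palm: the thumb has CMC
ab/adduction + flexion, MCP flexion and IP flexion; each finger has MCP
ab/adduction + flexion, PIP and DIP flexion.  Joint angles are computed
joint-to-joint from adjacent marker triplets (25 markers per hand: 4 per
digit, palm centre, 4 wrist), clipped to limits with a flag.  Grasp
contacts use a soft-finger model transmitting three force components
plus a torque about the contact normal (a 4-dimensional wrench basis per
contact).  The hand–object Jacobian is `H = (G⁺)ᵀ J_h`, where `J_h`
stacks the per-contact soft-finger Jacobians and `G` is the grasp map to
the tool origin; the torque identity `τ = Hᵀ f` holds by construction
for the minimum-norm contact-force distribution.

## Metrics

For a task direction `u` (unit vector) and the translational Jacobian
`J` (3×7 by default — the task demand is a pure force direction; the
full 6×7 is available):

* manipulability `ω = √det(J Jᵀ)` — distance from singularity;
* force-transmission ratio `α = (uᵀ J Jᵀ u)^(−1/2)` — the radius of the
  force ellipsoid `fᵀ(J Jᵀ)f = 1` along `u`;
* comfort `ε = 1 − (1/N_J) Σ_j β′_j ((q_j − q_j^r)/Q_j)²`, where `q^r`
  is the rest posture and `Q_j` the distance from rest to the nearer
  limit.  With β ≡ 1 this is the unweighted form; β′ (normalized to sum
  1) weights joints by their across-subject standard deviation, computed
  by `beta_from_cohort`.

Comfort can go below zero when a joint passes beyond the rest-to-nearer-
limit distance on the far side; the normalized composite is therefore
bounded above by 1 but not strictly non-negative at extreme postures.

α and the velocity-transmission ratio are reciprocal along principal
directions of `J Jᵀ` and their product is ≤ 1 elsewhere (Cauchy–
Schwarz); the tests check this corrected form of the force/velocity
duality.

## Task-demand extraction

Per-segment 3-D force samples (70 Hz) are enclosed in a minimum-volume
enclosing ellipsoid (Khachiyan's algorithm; default tolerance 1e-6,
iteration cap 10 000; forces are centred at their mean first, with a
no-centre switch).  The major axis (eigenvector of the smallest
eigenvalue of the shape matrix) is sign-canonicalized into the
negative-Z hemisphere — the task presses down — and near-isotropic
sections raise an ambiguity error instead of returning an arbitrary
direction.  Major axes of the successful segments are sign-aligned and
averaged into `f*`; its normalized vertical projection is the assistant-
hand demand `u_L` and its normalized horizontal projection the dominant-
hand demand `u_R`.  Inside the study pipeline the MVEE tolerance is
relaxed to 1e-4: only the axis direction feeds downstream, and the axis
is insensitive to the last two orders of volume slack while the
iteration count is far smaller.

## State-variable screening

Sobol variance-based indices of each metric over the joint box
(quasi-random Saltelli design via `scipy.stats.sobol_indices`,
`n_base = 2^12` by default) rank the joints; those with a sensitivity
ratio above 5% become lower-level state variables.  Selection uses the
total-order index by default (first-order by switch).  Negative
small-sample estimates are clamped to zero for selection but reported
raw.  The pipeline's default state variables — shoulder circumduction,
elbow flexion, forearm pronation/supination, wrist flexion, plus the
watch rotation θ — are shipped as a config default (the joints the
screen ranks as the strongest metric drivers; the union of all metrics'
selections at the 5% threshold is larger because the comfort index
responds to every joint, and is available through `screen_metrics`).

## Bi-level inverse optimization

The CNS is assumed to choose the state `x` (selected joints, plus θ for
the dominant arm) maximizing `Ψ(x|w) = Σ_i w_i κ_i Ψ_i(x)` with
`Ψ = (ω, α, ε)` and `κ_i = 1/max_x Ψ_i(x)` so each normalized metric
lies in [0, 1] over the box.  The watch rotation re-orients the
dominant-hand demand, `u_world = Rz(θ) u_task`; the assistant-hand
demand (0, 0, −1) is rotation-invariant, so θ belongs to the dominant
arm's state only.  Because α is quadratic in `u`, θ is identifiable only
mod π; the lower level folds θ into [−π/2, π/2) and the upper-level
distance uses the circular (mod-π) difference on θ.

The lower level runs seeded, vectorized differential evolution over the
box (stop when the population objective spread falls below e⁻⁵, the
protocol's stopping constant) followed by a bounded L-BFGS-B polish with
a batched central-difference gradient.  Normalization maxima use the
same solver with a larger population and top-3 polish, because the α
landscape is multimodal and an inconsistent κ between data generation
and recovery would bias the recovered weights.

The upper level minimizes `Φ(x(w), x*)` — the mean squared
state-variable error in rad² against the observed posture — over the
weight simplex, parameterized by two free coordinates with exact
Euclidean projection onto `{w ≥ 0, Σw = 1}`.  Each restart spends its
evaluation budget on a differential-evolution search plus a Nelder–Mead
refinement of the incumbent (a quarter of the budget), and the best of
the restarts is returned, renormalized.  Protocol defaults mirror the
solve protocol: 5 restarts, 500 upper-level trials; the validation suite
runs a reduced budget of 200 trials, which recovers planted weights to
L∞ ≲ 0.03 on both arms.  One fixed lower-level seed is used inside a
solve so that Φ is a deterministic function of the weights; the whole
result is reproducible from (seed, budgets).

Weights equal up to scale give identical lower-level solutions
(renormalized on entry), and scaling all raw metrics by a common factor
is absorbed by κ.

## Synthetic study

The generator emulates the two-group study design: 10 novice and 5
expert subjects by default.  Per subject:

* link lengths: 0.30/0.26/0.08 m ± 10% (uniform), shared across sides;
* true weights: logistic-normal draw (softmax of a Gaussian perturbation
  with σ = 0.10 in log-weight space) around the group template —
  novice right arm (0.393, 0.349, 0.258), expert right arm
  (0.394, 0.141, 0.465), i.e. experts shift dominant-arm weight from
  task compatibility toward comfort; the left templates are
  (0.334, 0.357, 0.309) and (0.393, 0.349, 0.258);
* posture: the lower-level optimum of the subject's own true weights —
  the planted truth is self-consistent by construction;
* markers: forward-kinematic tracker positions plus isotropic Gaussian
  noise with per-marker RMS displacement 1.63 mm (per-coordinate
  σ = 1.63/√3 mm), the reconstruction error scale of a multi-camera
  marking pipeline;
* force segments: 12 (novice) or 11 (expert) segments of ~3 s at 70 Hz;
  anisotropic Gaussian clouds (σ_major = 0.3 N, 3:1 axis ratio) about a
  1 N mean force along the dominant direction
  (−0.09, 0.19, −0.97)/‖·‖, with a 2° per-segment direction jitter;
  success is Bernoulli (0.575 novice, 0.835 expert).

All randomness flows through `numpy.random.Generator` (PCG64) from a
single `SeedSequence`, so a cohort is bit-identical under a fixed seed
(per `sides` configuration).  What the generator does **not** emulate:
time-resolved trajectories, tremor, skin-motion artefacts, correlated
marker noise, per-θ force re-orientation (force clouds are drawn in the
task frame for all subjects), anatomical left/right mirroring (both arms
use the same chain convention at different shoulder origins), or
mechanistic failure modes.  Passing tests therefore demonstrate that the
pipeline recovers what its own model class generates — a planted-truth
validation — not that the model is correct for real recordings.

## Study pipeline and statistics

`run_study` chains markers → IK → metrics → demand extraction (from the
expert group's successful segments) → per-subject, per-arm inverse
optimization → alignment angles (watch rotation θ; ϑ, the horizontal
angle of the arm force-ellipsoid major axis from +X; δ, the included
angle between the demand and that axis, folded into [0, 90°]) → one-way
ANOVA group contrasts.  Angles are degrees in reports, radians
internally.  p-values are descriptive; no multiple-testing correction is
applied.  The comfort basis of the inverse optimization is uniform-β by
default: synthetic postures are planted through the same basis, and a
cohort-derived β would make the recovery basis depend circularly on the
recovered cohort; cohort-β (the across-subject standard deviation form)
is available via `StudyConfig(beta_mode="cohort")` for real recordings.

The group-contrast experiment generates cohorts whose groups differ in
the planted dominant-arm comfort weight (0.465 vs 0.258 templates)
alongside matched null cohorts (both groups on the novice template), and
asks whether the right-arm comfort-weight ANOVA flags the gap and not
the null.  The shipped problem sizes — 6 + 4 subjects per cohort, 10
replicates per condition, 1 restart with a 48-trial upper budget per
subject — are the package's scaled study sizes for routine validation;
the full protocol (10 + 5 subjects, 5 restarts, 500 trials) is available
through the same functions.

## Numerical choices and degenerate inputs

* IK: geometrically inconsistent markers still return a flagged fit with
  a large residual; collinear marker sets fall back to a rest-posture
  start and are flagged `degenerate`; a missing marker raises an error
  naming it.
* Metrics: `α` raises an "unbounded transmission" error when `u` lies in
  the null space of `Jᵀ` rather than returning ∞.
* MVEE: rank-deficient clouds raise a degenerate-ellipsoid error
  carrying the deficient direction.
* ANOVA: all-identical data returns F = 0 with a `degenerate` flag.
* Sobol: non-finite cost evaluations are counted and replaced by the
  finite mean; more than 1% rejections aborts the screen.
* Solver tie-breaks: θ folding (above); the lower-level DE population is
  initialized with a Sobol' sequence, making results reproducible across
  platforms for a fixed seed.

## Known limitations

The arm model omits scapular motion and models the shoulder as three
intersecting axes; the comfort index is kinematic only (no
torque/energy/jerk terms); the inverse optimization treats the posture
as quasi-static and ignores finger joints; identifiability of the
weights rests on the three metrics having distinguishable gradients near
the optimum, which degrades for extreme (near-vertex) weight vectors
where the lower-level landscape becomes multimodal.
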