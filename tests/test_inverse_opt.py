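"""Bi-level inverse optimization: normalization, lower/upper levels, beta."""

import numpy as np
import pytest

from bimanip.inverse_opt import (
    ArmStateSpace,
    CostBasis,
    InverseOptError,
    WeightVector,
    beta_from_cohort,
    lower_level_solve,
    normalization_constants,
    phi_joint_mse,
    project_simplex,
    upper_level_solve,
    with_normalization,
)
from bimanip.metrics import BetaWeights
from bimanip.skeleton import ArmSkeleton
from bimanip.synthetic import DEFAULT_FORCE_DIRECTION
from bimanip.task_demand import decompose_demand


@pytest.fixture(scope="module")
def right_basis():
    skel = ArmSkeleton(side="right")
    space = ArmStateSpace(skel, include_theta=True)
    demand = decompose_demand(DEFAULT_FORCE_DIRECTION)
    return with_normalization(CostBasis(space, u_task=demand.u_right), seed=3)


class TestWeightVector:
    def test_simplex_validation(self):
        with pytest.raises(InverseOptError):
            WeightVector(np.array([0.5, 0.5, 0.5]))
        with pytest.raises(InverseOptError):
            WeightVector(np.array([1.2, -0.1, -0.1]))
        w = WeightVector.normalized([2.0, 1.0, 1.0])
        assert np.allclose(w.values, [0.5, 0.25, 0.25])

    def test_project_simplex_properties(self, rng):
        for _ in range(50):
            v = rng.standard_normal(3) * 2
            p = project_simplex(v)
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
        # already-on-simplex points are fixed points
        w = np.array([0.2, 0.3, 0.5])
        assert np.allclose(project_simplex(w), w)


class TestNormalizationConstants:
    def _basis_1d(self, fun):
        """A tiny stand-in basis exposing raw_metrics over a box."""
        class Box:
            bounds = np.array([[0.0, 2.0]])
        class B:
            space = Box()
            def raw_metrics(self, X):
                v = fun(X[:, 0])
                return np.column_stack([v, v, v])
        return B()

    def test_linear_metric(self):
        basis = self._basis_1d(lambda x: x)
        kappa = normalization_constants(basis, seed=0)
        assert np.allclose(kappa, 0.5, rtol=1e-6)

    def test_constant_metric(self):
        basis = self._basis_1d(lambda x: np.full_like(x, 4.0))
        kappa = normalization_constants(basis, seed=0)
        assert np.allclose(kappa, 0.25, rtol=1e-9)

    def test_quadratic_bowl_matches_grid_oracle(self):
        class Box:
            bounds = np.array([[-1.0, 2.0], [-1.0, 1.5]])

        def f(X):
            return 3.0 - (X[:, 0] - 1.7) ** 2 - (X[:, 1] + 0.8) ** 2

        class B:
            space = Box()
            def raw_metrics(self, X):
                v = f(X)
                return np.column_stack([v, v, v])

        kappa = normalization_constants(B(), seed=1)
        g = np.meshgrid(np.linspace(-1, 2, 301), np.linspace(-1, 1.5, 251))
        grid_max = f(np.column_stack([g[0].ravel(), g[1].ravel()])).max()
        assert np.allclose(1.0 / kappa, grid_max, rtol=0.01)

    def test_nonpositive_metric_rejected(self):
        basis = self._basis_1d(lambda x: -1.0 - x)
        with pytest.raises(InverseOptError, match="non-positive"):
            normalization_constants(basis, seed=0)

    def test_normalized_metrics_bounded_by_one(self, right_basis, rng):
        b = right_basis.space.bounds
        X = b[:, 0] + (b[:, 1] - b[:, 0]) * rng.uniform(size=(300, b.shape[0]))
        raw = right_basis.raw_metrics(X) * right_basis.kappa
        assert np.nanmax(raw) <= 1.0 + 1e-6


class TestLowerLevel:
    def test_comfort_only_returns_rest(self, right_basis):
        """With all weight on comfort the optimum is the rest posture
        (interior of the box)."""
        res = lower_level_solve(WeightVector(np.array([0.0, 0.0, 1.0])),
                                right_basis, seed=5)
        rest_sel = right_basis.space.skeleton.rest_posture[
            list(right_basis.space.selected)]
        assert np.allclose(res.x[:4], rest_sel, atol=1e-4)

    def test_composite_objective_in_unit_interval(self, right_basis):
        res = lower_level_solve(WeightVector(np.array([0.4, 0.35, 0.25])),
                                right_basis, seed=5)
        assert 0.0 <= res.objective <= 1.0 + 1e-9

    def test_scale_invariance_of_weights(self, right_basis):
        r1 = lower_level_solve([0.4, 0.35, 0.25], right_basis, seed=5)
        r2 = lower_level_solve([4.0, 3.5, 2.5], right_basis, seed=5)
        assert np.allclose(r1.x, r2.x)

    def test_manipulability_only_matches_grid_oracle(self):
        """2-joint toy problem: the lower level matches a dense grid argmax."""
        skel = ArmSkeleton(side="right")
        space = ArmStateSpace(skel, selected=(1, 3), include_theta=False)
        basis = CostBasis(space, u_task=np.array([0.0, 0.0, -1.0]))
        basis.kappa = np.array([1.0, 1.0, 1.0])
        w = WeightVector(np.array([1.0, 0.0, 0.0]))
        res = lower_level_solve(w, basis, seed=2)
        b = space.bounds
        g1, g2 = np.meshgrid(np.linspace(b[0, 0], b[0, 1], 201),
                             np.linspace(b[1, 0], b[1, 1], 201))
        X = np.column_stack([g1.ravel(), g2.ravel()])
        vals = basis.raw_metrics(X)[:, 0]
        xg = X[np.argmax(vals)]
        cell = np.array([b[0, 1] - b[0, 0], b[1, 1] - b[1, 0]]) / 200
        assert np.all(np.abs(res.x - xg) <= cell)
        assert res.objective >= vals.max() - 1e-6

    def test_deterministic_given_seed(self, right_basis):
        r1 = lower_level_solve([0.4, 0.35, 0.25], right_basis, seed=9)
        r2 = lower_level_solve([0.4, 0.35, 0.25], right_basis, seed=9)
        assert np.array_equal(r1.x, r2.x)
        assert r1.objective == r2.objective


class TestUpperLevel:
    def test_recovers_planted_weights(self, right_basis):
        w_true = WeightVector(np.array([0.40, 0.35, 0.25]))
        x_star = lower_level_solve(w_true, right_basis, seed=21).x
        res = upper_level_solve(x_star, right_basis, restarts=2, budget=100,
                                seed=4)
        assert np.max(np.abs(res.weights.values - w_true.values)) <= 0.10
        # solution never worse than the evaluated truth
        x_truth = lower_level_solve(w_true, right_basis,
                                    seed=res.lower_seed).x
        assert res.phi <= phi_joint_mse(x_truth, x_star,
                                        right_basis.space) + 1e-6

    def test_weights_on_simplex(self, right_basis):
        x_star = lower_level_solve([0.3, 0.3, 0.4], right_basis, seed=21).x
        res = upper_level_solve(x_star, right_basis, restarts=2, budget=36,
                                seed=8)
        for t in res.restarts:
            assert t.weights.min() >= -1e-12
            assert t.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_full_determinism(self, right_basis):
        x_star = lower_level_solve([0.4, 0.35, 0.25], right_basis, seed=21).x
        r1 = upper_level_solve(x_star, right_basis, restarts=2, budget=36, seed=6)
        r2 = upper_level_solve(x_star, right_basis, restarts=2, budget=36, seed=6)
        assert np.array_equal(r1.weights.values, r2.weights.values)
        assert r1.phi == r2.phi
        assert [t.phi for t in r1.restarts] == [t.phi for t in r2.restarts]

    def test_observed_outside_bounds_rejected(self, right_basis):
        bad = right_basis.space.bounds[:, 1] + 0.5
        with pytest.raises(InverseOptError, match="outside"):
            upper_level_solve(bad, right_basis, restarts=1, budget=24, seed=0)

    def test_kappa_absorbs_common_metric_scale(self):
        """Scaling all raw metrics by a common factor leaves the recovered
        weights unchanged (kappa absorbs it)."""
        skel = ArmSkeleton(side="right")
        space = ArmStateSpace(skel, include_theta=True)
        demand = decompose_demand(DEFAULT_FORCE_DIRECTION)
        base = CostBasis(space, u_task=demand.u_right)

        class Scaled(CostBasis):
            def raw_metrics(self, X):
                return 7.5 * super().raw_metrics(X)

        scaled = Scaled(space, u_task=demand.u_right)
        k1 = normalization_constants(base, seed=3)
        k2 = normalization_constants(scaled, seed=3)
        assert np.allclose(k1, 7.5 * k2, rtol=1e-6)
        base.kappa, scaled.kappa = k1, k2
        w = WeightVector(np.array([0.4, 0.35, 0.25]))
        x1 = lower_level_solve(w, base, seed=11).x
        x2 = lower_level_solve(w, scaled, seed=11).x
        assert np.allclose(x1, x2, atol=1e-9)


class TestBetaFromCohort:
    def test_identical_subjects_rejected(self):
        Q = np.tile(np.linspace(0, 1, 7), (3, 1))
        with pytest.raises(InverseOptError):
            beta_from_cohort(Q)

    def test_single_varying_joint_gives_indicator(self):
        Q = np.zeros((4, 7))
        Q[:, 2] = [0.1, 0.2, 0.3, 0.4]
        b = beta_from_cohort(Q)
        expected = np.zeros(7)
        expected[2] = 1.0
        assert np.allclose(b.weights, expected)

    def test_matches_two_pass_std(self, rng):
        Q = rng.standard_normal((8, 7))
        b = beta_from_cohort(Q)
        # independent two-pass standard deviation
        stds = []
        for j in range(7):
            m = sum(Q[:, j]) / 8
            stds.append((sum((Q[i, j] - m) ** 2 for i in range(8)) / 8) ** 0.5)
        stds = np.array(stds)
        assert np.allclose(b.weights, stds / stds.sum(), atol=1e-12)

    def test_is_valid_beta(self, rng):
        b = beta_from_cohort(rng.standard_normal((5, 7)))
        assert isinstance(b, BetaWeights)
        assert b.weights.sum() == pytest.approx(1.0, abs=1e-9)
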