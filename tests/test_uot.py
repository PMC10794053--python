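import numpy as np
import pytest

from shootcount import (
    PointAnnotation,
    cost_matrix,
    perspective_coeff,
    solve_uot,
    uot_loss_and_grad,
    uot_objective,
)
from shootcount.density import DensityMap, density_from_points
from shootcount.uot import (
    PredictedDensity,
    TargetDots,
    composite_loss,
    composite_loss_and_grad,
    grid_coords,
    smooth_l1,
)


class TestPerspectiveCoeff:
    def test_mean_of_heights(self):
        assert perspective_coeff(0.4, 0.6) == pytest.approx(0.5)

    @pytest.mark.parametrize("h", [0.1, 0.5, 1.0])
    def test_equal_heights_fixed_point(self, h):
        assert perspective_coeff(h, h) == pytest.approx(h)

    def test_zero_height_rejected(self):
        with pytest.raises(ValueError):
            perspective_coeff(0.0, 0.5)


class TestCostMatrix:
    def test_coincident_points_cost_one_under_perspective(self):
        p = np.array([[5.0, 5.0]])
        C = cost_matrix(p, p, "perspective", image_height=10.0)
        assert C.entries[0, 0] == pytest.approx(1.0)

    def test_half_height_pair_gives_exp_one(self):
        # normalized distance 0.5, both points at normalized height 0.5
        H = 100.0
        C = cost_matrix(
            np.array([[0.0, 49.0]]), np.array([[50.0, 49.0]]), "perspective", H
        )
        assert C.entries[0, 0] == pytest.approx(np.e)

    def test_perspective_cost_decreasing_in_eta(self):
        # same planar distance, increasing heights -> increasing eta -> lower cost
        H = 100.0
        costs = []
        for y in [4.0, 24.0, 49.0, 74.0, 99.0]:
            C = cost_matrix(
                np.array([[0.0, y]]), np.array([[30.0, y]]), "perspective", H
            )
            costs.append(C.entries[0, 0])
        assert all(c1 > c2 for c1, c2 in zip(costs, costs[1:]))

    def test_kind_relationships(self):
        xs = np.array([[0.0, 0.0]])
        ys = np.array([[3.0, 4.0]])
        e = cost_matrix(xs, ys, "euclid", 10.0).entries[0, 0]
        s = cost_matrix(xs, ys, "squared", 10.0).entries[0, 0]
        x = cost_matrix(xs, ys, "exp", 10.0).entries[0, 0]
        assert e == pytest.approx(0.5)
        assert s == pytest.approx(0.25)
        assert x == pytest.approx(np.exp(0.5))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            cost_matrix(np.zeros((1, 2)), np.zeros((1, 2)), "manhattan")

    def test_exp_requires_height(self):
        with pytest.raises(ValueError):
            cost_matrix(np.zeros((1, 2)), np.zeros((1, 2)), "exp")


class TestSolveUot:
    def test_empty_mass_gives_zero_plan(self):
        plan = solve_uot(np.array([0.0]), np.array([0.0]), np.array([[1.0]]))
        assert plan.objective == 0.0
        assert (plan.plan == 0).all()

    def test_1x1_matches_dense_grid_oracle(self):
        a, b, C = np.array([1.0]), np.array([1.0]), np.array([[1.0]])
        eps, tau = 0.05, 0.5
        p = np.arange(0.0, 2.0001, 1e-5)
        xlogx = np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0)
        oracle = (C[0, 0] * p - eps * xlogx + tau * (p - 1) ** 2 + tau * np.abs(p - 1)).min()
        plan = solve_uot(a, b, C, eps, tau)
        assert plan.objective == pytest.approx(oracle, rel=1e-4, abs=1e-4)

    def test_near_diagonal_costs_concentrate_plan(self):
        a = np.array([1.0, 1.0])
        b = np.array([1.0, 1.0])
        C = np.array([[1e-4, 5.0], [5.0, 1e-4]])
        plan = solve_uot(a, b, C, eps=1e-3, tau=50.0)
        off = plan.plan[0, 1] + plan.plan[1, 0]
        assert off < 0.05 * plan.plan.sum()

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_uot(np.array([np.nan]), np.array([1.0]), np.array([[1.0]]))

    def test_max_iter_exhaustion_flags_not_converged(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(0.5, 1, 3), rng.uniform(0.5, 1, 3)
        C = rng.uniform(0.1, 2, (3, 3))
        plan = solve_uot(a, b, C, tol=1e-16, max_iter=3, refine=False)
        assert not plan.converged
        assert np.isfinite(plan.objective)

    def test_marginal_fidelity_improves_with_tau(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0.2, 1.5, 4)
        b = rng.uniform(0.2, 1.5, 3)
        C = rng.uniform(0.1, 2.0, (4, 3))
        gaps = []
        for tau in (0.05, 0.5, 5.0, 50.0):
            plan = solve_uot(a, b, C, eps=0.05, tau=tau, refine=False)
            gaps.append(np.abs(plan.plan.sum(axis=1) - a).sum() / a.sum())
        assert all(g1 >= g2 - 1e-9 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < gaps[0]


class TestLossAndGrad:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(17)
        n, m = 3, 2
        a = rng.uniform(0.1, 1.0, n)
        coords = rng.uniform(0, 8, (n, 2))
        tc = rng.uniform(0, 8, (m, 2))
        C = cost_matrix(coords, tc, "perspective", 8.0)
        pred = PredictedDensity(a, coords)
        dots = TargetDots(np.ones(m), tc)
        _, grad, _ = uot_loss_and_grad(pred, dots, C)
        h = 1e-5
        for i in range(n):
            ap, am = a.copy(), a.copy()
            ap[i] += h
            am[i] -= h
            lp = uot_loss_and_grad(PredictedDensity(ap, coords), dots, C)[0]
            lm = uot_loss_and_grad(PredictedDensity(am, coords), dots, C)[0]
            fd = (lp - lm) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-3, abs=1e-5)

    def test_doubling_tau_doubles_penalties_at_fixed_plan(self):
        rng = np.random.default_rng(23)
        P = rng.uniform(0, 1, (3, 2))
        a, b = rng.uniform(0.2, 1, 3), rng.uniform(0.2, 1, 2)
        C = rng.uniform(0.1, 2, (3, 2))
        base = uot_objective(P, a, b, C, eps=0.05, tau=0.5)
        doubled = uot_objective(P, a, b, C, eps=0.05, tau=1.0)
        transport = (C * P).sum() - 0.05 * np.where(P > 0, P * np.log(P), 0).sum()
        assert doubled - transport == pytest.approx(2 * (base - transport), rel=1e-12)


class TestCompositeLoss:
    def _setup(self, count=4, size=16):
        rng = np.random.default_rng(31)
        pts = PointAnnotation(
            "c", size, size, rng.uniform(1, size - 1, (count, 2))
        )
        gt = density_from_points(pts)
        return pts, gt

    def test_perfect_prediction_zeroes_count_and_pixel_terms(self):
        pts, gt = self._setup()
        lb = composite_loss(gt, pts, gt)
        assert lb.count_loss == pytest.approx(0.0, abs=1e-9)
        assert lb.pixel_mse == pytest.approx(0.0, abs=1e-12)

    def test_half_count_offset_in_quadratic_zone(self):
        pts, gt = self._setup()
        bumped = DensityMap(gt.grid * (1 + 0.5 / gt.count), gt.stride, gt.source_id)
        lb = composite_loss(bumped, pts, gt)
        assert lb.count_loss == pytest.approx(0.125, abs=1e-6)

    def test_total_is_weighted_sum(self):
        pts, gt = self._setup()
        rng = np.random.default_rng(5)
        pred = DensityMap(np.abs(gt.grid + rng.normal(0, 0.01, gt.grid.shape)))
        lb = composite_loss(pred, pts, gt, lambda1=0.1, lambda2=0.01)
        assert lb.total == pytest.approx(
            lb.count_loss + 0.1 * lb.ot_loss + 0.01 * lb.pixel_mse, abs=1e-9
        )

    def test_shape_mismatch_rejected(self):
        pts, gt = self._setup()
        with pytest.raises(ValueError):
            composite_loss(DensityMap(np.zeros((3, 3))), pts, gt)

    def test_gradient_shape_matches_grid(self):
        pts, gt = self._setup()
        lb, grad, _ = composite_loss_and_grad(gt, pts, gt)
        assert grad.shape == gt.grid.shape
        assert np.isfinite(grad).all()


def test_smooth_l1_quadratic_and_linear_zones():
    assert smooth_l1(0.5, 0.0) == pytest.approx(0.125)
    assert smooth_l1(3.0, 0.0) == pytest.approx(2.5)


def test_grid_coords_are_pixel_centres():
    coords = grid_coords((2, 3))
    assert coords.shape == (6, 2)
    np.testing.assert_array_equal(coords[0], [0.5, 0.5])
    np.testing.assert_array_equal(coords[-1], [2.5, 1.5])
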