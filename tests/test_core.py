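"""Unit and property tests for the LP hyperplane fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lpda
from lpda.core import (
    TwoGroupData, build_lp, centroids, check_separability, fit_hyperplane,
    predict_binary, separation_error, solve_lp,
)
from helpers import grid_min_separation_error, random_instance


class TestTwoGroupData:
    def test_raw_weights_are_renormalized_per_group(self):
        d = TwoGroupData([[0.0], [1.0]], [[2.0]], m=[2.0, 6.0], w=[5.0], labels=("A", "B"))
        assert np.allclose(d.m, [0.25, 0.75])
        assert d.w == pytest.approx([1.0])
        assert abs(d.m.sum() - 1) < 1e-10 and abs(d.w.sum() - 1) < 1e-10

    @pytest.mark.parametrize("kwargs", [
        dict(X=[[1.0, 2.0]], Y=[[1.0]]),                       # feature mismatch
        dict(X=[[np.nan]], Y=[[1.0]]),                          # non-finite
        dict(X=[[1.0]], Y=[[2.0]], m=[0.0]),                    # non-positive weight
        dict(X=[[1.0]], Y=[[2.0]], m=[1.0, 1.0]),               # weight length
        dict(X=[[1.0]], Y=[[2.0]], labels=("A", "A")),          # identical labels
    ])
    def test_invalid_construction_rejected(self, kwargs):
        with pytest.raises(lpda.ValidationError):
            TwoGroupData(**{"labels": ("A", "B"), **kwargs})

    def test_default_weights_are_equal(self):
        d = TwoGroupData(np.zeros((3, 2)), np.ones((5, 2)))
        assert np.allclose(d.m, 1 / 3) and np.allclose(d.w, 1 / 5)


class TestSeparationError:
    def test_zero_vector_gives_two(self, separable_gaussians):
        assert separation_error(np.zeros(2), 0.5, separable_gaussians) == pytest.approx(2.0)

    @pytest.mark.parametrize("a,b,expected", [
        ([1.0], 0.0, 0.0),    # every margin satisfied with slack
        ([1.0], 5.0, 3.5),    # offset pushed past both clouds: both X points violate
    ])
    def test_separable_1d_values(self, separable_1d, a, b, expected):
        assert separation_error(a, b, separable_1d) == pytest.approx(expected)

    def test_single_point_arithmetic(self):
        d = TwoGroupData([[0.5]], [[-0.5]], labels=("A", "B"))
        # max(1 - 0.5, 0) + max(-0.5 + 1, 0) = 1
        assert separation_error([1.0], 0.0, d) == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self, separable_gaussians):
        with pytest.raises(lpda.ValidationError):
            separation_error([1.0], 0.0, separable_gaussians)


class TestBuildLP:
    @pytest.mark.parametrize("n1,n2,p", [(1, 1, 1), (2, 3, 4)])
    def test_shapes(self, rng, n1, n2, p):
        d = TwoGroupData(rng.normal(size=(n1, p)), rng.normal(size=(n2, p)),
                         labels=("A", "B"))
        prob = build_lp(d)
        assert prob.n_variables == p + 1 + n1 + n2
        assert prob.n_constraints == n1 + n2
        assert np.allclose(prob.c[: p + 1], 0.0)
        assert np.allclose(prob.c[p + 1: p + 1 + n1], d.m)
        assert np.allclose(prob.c[p + 1 + n1:], d.w)

    def test_zero_hyperplane_unit_slacks_always_feasible(self, rng):
        d = random_instance(rng)
        prob = build_lp(d)
        z = np.concatenate([np.zeros(d.p + 1), np.ones(d.n1 + d.n2)])
        assert np.all(prob.A_ub @ z <= prob.b_ub + 1e-12)
        assert prob.c @ z == pytest.approx(2.0)


class TestSolveLP:
    def test_separable_instance_reaches_zero(self, separable_1d):
        sol = solve_lp(build_lp(separable_1d))
        assert sol.objective == pytest.approx(0.0, abs=1e-8)
        assert check_separability(sol)

    def test_symmetric_instance_is_stuck_at_two(self, symmetric_1d):
        sol = solve_lp(build_lp(symmetric_1d))
        assert sol.objective == pytest.approx(2.0, abs=1e-8)
        assert sol.solver_status in ("optimal", "degenerate_zero_a")

    def test_solution_internal_consistency(self, rng):
        for _ in range(10):
            d = random_instance(rng)
            sol = solve_lp(build_lp(d))
            assert 0.0 <= sol.objective <= 2.0 + 1e-8
            assert sol.objective == pytest.approx(
                float(d.m @ sol.u + d.w @ sol.v), abs=1e-8)
            assert np.all(sol.u >= np.maximum(sol.b + 1 - d.X @ sol.a, 0) - 1e-8)
            assert np.all(sol.v >= np.maximum(d.Y @ sol.a - sol.b + 1, 0) - 1e-8)
            # (P1) <-> (P): objective equals the separation error at the optimum
            assert separation_error(sol.a, sol.b, d) == pytest.approx(
                sol.objective, abs=1e-6)


class TestGridOracle:
    def test_lp_matches_dense_grid_search(self, rng):
        """The LP optimum equals the direct minimum of f on tiny instances."""
        for _ in range(12):
            d = random_instance(rng, max_n=5)
            sol = solve_lp(build_lp(d))
            grid_val, _, _ = grid_min_separation_error(d)
            assert sol.objective <= grid_val + 1e-7
            assert grid_val - sol.objective <= 0.02


class TestFitHyperplane:
    def test_separable_fit_satisfies_all_margins(self, separable_1d):
        h, sol = fit_hyperplane(separable_1d)
        assert sol.objective == pytest.approx(0.0, abs=1e-8)
        assert np.all(separable_1d.X @ h.a >= h.b + 1 - 1e-8)
        assert np.all(separable_1d.Y @ h.a <= h.b - 1 + 1e-8)
        pred = predict_binary(h, np.vstack([separable_1d.X, separable_1d.Y]),
                              separable_1d.labels)
        assert list(pred) == ["A", "A", "B", "B"]

    def test_coincident_centroids_raise_degenerate_error(self, symmetric_1d):
        with pytest.raises(lpda.DegenerateDataError):
            fit_hyperplane(symmetric_1d)

    def test_group_swap_flips_predictions(self, overlapping_gaussians):
        d = overlapping_gaussians
        h1, s1 = fit_hyperplane(d)
        h2, s2 = fit_hyperplane(d.swapped())
        assert s1.objective == pytest.approx(s2.objective, abs=1e-7)
        pts = np.vstack([d.X, d.Y])
        p1 = predict_binary(h1, pts, ("A", "B"))
        p2 = predict_binary(h2, pts, ("B", "A"))
        # ties are measure-zero here; predictions must coincide
        assert np.array_equal(p1, p2)

    def test_nonzero_a_recovered_when_centroids_differ(self):
        # duplicated points across groups force v(P) = 2 on that pair, but the
        # centroids differ, so a discriminant hyperplane must still come back
        d = TwoGroupData([[0.0], [4.0]], [[0.0]], labels=("A", "B"))
        h, sol = fit_hyperplane(d)
        assert np.linalg.norm(h.a) > 1e-8
        assert sol.objective <= 2.0 + 1e-8


class TestCentroids:
    def test_equal_weights_mean(self):
        d = TwoGroupData([[0.0, 0.0], [2.0, 2.0]], [[5.0, 5.0]], labels=("A", "B"))
        xbar, ybar = centroids(d)
        assert np.allclose(xbar, [1.0, 1.0]) and np.allclose(ybar, [5.0, 5.0])

    def test_weighted_mean(self):
        d = TwoGroupData([[0.0], [4.0]], [[9.0]], m=[0.25, 0.75], labels=("A", "B"))
        xbar, ybar = centroids(d)
        assert xbar == pytest.approx([3.0])
        assert ybar == pytest.approx([9.0])  # a single point is its own centroid


class TestCheckSeparability:
    @pytest.mark.parametrize("objective,expected", [
        (0.0, True), (2.0, False), (0.5e-8, True), (1.1e-8, False),
    ])
    def test_tolerance_rule(self, objective, expected, separable_1d):
        sol = solve_lp(build_lp(separable_1d))
        sol = type(sol)(a=sol.a, b=sol.b, u=sol.u, v=sol.v, objective=objective,
                        solver_status="optimal")
        assert check_separability(sol, tol=1e-8) is expected


class TestPredictBinary:
    def test_sign_rule_and_tie_convention(self):
        h = lpda.Hyperplane([1.0, 0.0], 0.0)
        pred = predict_binary(h, [[3.0, -7.0], [0.0, 5.0], [-2.0, 0.0]], ("A", "B"))
        assert list(pred) == ["A", "A", "B"]  # the a'x = b tie goes to the first label

    def test_dimension_mismatch_rejected(self):
        h = lpda.Hyperplane([1.0, 0.0], 0.0)
        with pytest.raises(lpda.ValidationError):
            predict_binary(h, [[1.0]], ("A", "B"))


def _instances(max_side=3, max_p=2):
    """Hypothesis strategy for small two-group instances."""
    def build(p, n1, n2, draw_flat):
        vals = np.array(draw_flat[: (n1 + n2) * p])
        X = vals[: n1 * p].reshape(n1, p)
        Y = vals[n1 * p:].reshape(n2, p)
        return TwoGroupData(X, Y, labels=("A", "B"))
    coords = st.floats(-5, 5, allow_nan=False)
    return st.tuples(
        st.integers(1, max_p), st.integers(1, max_side), st.integers(1, max_side),
    ).flatmap(lambda t: st.lists(
        coords, min_size=(t[1] + t[2]) * t[0], max_size=(t[1] + t[2]) * t[0],
    ).map(lambda flat: build(t[0], t[1], t[2], flat)))


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=_instances())
    def test_objective_bounds(self, data):
        sol = solve_lp(build_lp(data))
        assert -1e-9 <= sol.objective <= 2.0 + 1e-8

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(data=_instances(), t=st.lists(st.floats(-10, 10, allow_nan=False),
                                         min_size=2, max_size=2))
    def test_translation_leaves_objective_unchanged(self, data, t):
        shift = np.array(t[: data.p])
        moved = TwoGroupData(data.X + shift, data.Y + shift, data.m, data.w, data.labels)
        v0 = solve_lp(build_lp(data)).objective
        v1 = solve_lp(build_lp(moved)).objective
        assert v1 == pytest.approx(v0, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(data=_instances(), c=st.floats(0.125, 8, allow_nan=False))
    def test_positive_scaling_leaves_objective_unchanged(self, data, c):
        scaled = TwoGroupData(c * data.X, c * data.Y, data.m, data.w, data.labels)
        v0 = solve_lp(build_lp(data)).objective
        v1 = solve_lp(build_lp(scaled)).objective
        assert v1 == pytest.approx(v0, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(data=_instances())
    def test_group_swap_leaves_objective_unchanged(self, data):
        v0 = solve_lp(build_lp(data)).objective
        v1 = solve_lp(build_lp(data.swapped())).objective
        assert v1 == pytest.approx(v0, abs=1e-6)

    def test_translation_and_scaling_preserve_predictions(self, rng,
                                                          overlapping_gaussians):
        d = overlapping_gaussians
        pts = rng.normal(size=(40, d.p), scale=2.0)
        h0, _ = fit_hyperplane(d)
        base = predict_binary(h0, pts, d.labels)
        shift = np.array([3.0, -7.0])
        h1, _ = fit_hyperplane(TwoGroupData(d.X + shift, d.Y + shift, d.m, d.w, d.labels))
        assert np.array_equal(predict_binary(h1, pts + shift, d.labels), base)
        h2, _ = fit_hyperplane(TwoGroupData(2.5 * d.X, 2.5 * d.Y, d.m, d.w, d.labels))
        assert np.array_equal(predict_binary(h2, 2.5 * pts, d.labels), base)


class TestSeparabilityCertificate:
    def test_zero_objective_iff_margins_hold(self, rng):
        """v(P)=0 exactly when every margin constraint holds at the optimum."""
        seen = {True: 0, False: 0}
        for shift in [0.0, 0.5, 1.0, 4.0, 8.0]:
            d = random_instance(rng, p=2, shift=shift)
            sol = solve_lp(build_lp(d))
            margins_ok = (np.all(d.X @ sol.a >= sol.b + 1 - 1e-7)
                          and np.all(d.Y @ sol.a <= sol.b - 1 + 1e-7))
            assert margins_ok == check_separability(sol, tol=1e-7)
            seen[margins_ok] += 1
        assert seen[True] > 0 and seen[False] > 0  # both regimes exercised
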