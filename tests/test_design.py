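"""Budgeted experimental design, cost models, and theory utilities."""

import numpy as np
import pytest

from grextrap import (
    BoundKernel,
    CostModel,
    DesignInfeasibleError,
    DesignProblem,
    Matern,
    MonomialBound,
    Wendland,
    box_fill_distance,
    design_objective,
    fill_distance_condition,
    gamma_d,
    optimal_design,
)


@pytest.fixture
def rough_bk():
    # first-order method, rough (exponential) kernel: the Example-10 setting
    return BoundKernel(MonomialBound(1), Matern(0))


class TestCostModel:
    def test_inverse_power_default(self):
        c = CostModel("inverse_power")
        assert c(0.25) == pytest.approx(4.0)

    def test_inverse_power_multidim(self):
        c = CostModel("inverse_power", exponents=[3.0, 1.0], scale=[2.0, 1.0])
        assert c([0.5, 0.25]) == pytest.approx(2 * 8.0 + 4.0)

    def test_tabulated(self):
        c = CostModel("tabulated", table={0.5: 10.0})
        assert c(0.5) == 10.0
        with pytest.raises(KeyError):
            c(0.7)

    def test_validation(self):
        with pytest.raises(ValueError):
            CostModel("inverse_power", exponents=[-1.0])
        with pytest.raises(ValueError):
            CostModel("tabulated", table={})


class TestObjective:
    def test_single_point(self, rough_bk):
        x = 0.5
        kbb = rough_bk(np.array([[x]]))[0, 0]
        assert design_objective(np.array([[x]]), rough_bk) == pytest.approx(
            1.0 / kbb
        )

    def test_diagonal_two_points(self):
        # compactly supported kernel with distant points: K diagonal
        bk = BoundKernel(MonomialBound(1), Wendland(0, lengthscales=0.1))
        X = np.array([[0.3], [0.9]])
        K = bk.gram(X)
        assert K[0, 1] == 0.0
        expected = 1.0 / K[0, 0] + 1.0 / K[1, 1]
        assert design_objective(X, bk) == pytest.approx(expected, rel=1e-10)

    def test_monotone_under_inclusion(self, rough_bk, rng):
        # adding a design point never decreases the objective
        for _ in range(100):
            n = int(rng.integers(2, 7))
            X = np.sort(rng.uniform(0.05, 1.0, n))
            k = int(rng.integers(1, n))
            sub = rng.choice(n, size=k, replace=False)
            o_small = design_objective(X[sub], rough_bk)
            o_big = design_objective(X, rough_bk)
            assert o_big >= o_small * (1 - 1e-8)


class TestOptimalDesign:
    def test_saturation_at_large_budget(self, rough_bk):
        D = np.linspace(0.1, 1.0, 8)
        cost = CostModel("inverse_power")
        total = sum(1.0 / D)
        sol = optimal_design(DesignProblem(D, rough_bk, cost, 2 * total))
        assert sol.X.shape[0] == 8
        assert sol.optimality_flag

    def test_exploitative_at_tight_budget(self, rough_bk):
        # rough kernel: cost concentrates on the smallest affordable x plus
        # a residual cheap point or two
        D = np.linspace(0.05, 1.0, 20)
        cost = CostModel("inverse_power")
        sol = optimal_design(DesignProblem(D, rough_bk, cost, 25.0),
                             mode="greedy")
        assert D[np.argmax([cost(x) for x in D])] in sol.X[:, 0]
        assert sol.X.shape[0] <= 4

    def test_greedy_near_exhaustive(self, rough_bk, rng):
        cost = CostModel("inverse_power")
        for _ in range(5):
            D = np.sort(rng.uniform(0.05, 1.0, 10))
            budget = 0.6 * sum(1.0 / D)
            prob = DesignProblem(D, rough_bk, cost, budget)
            ex = optimal_design(prob, "exhaustive")
            gr = optimal_design(prob, "greedy")
            assert gr.objective >= 0.9 * ex.objective
            assert not gr.optimality_flag and ex.optimality_flag

    def test_invariant_to_candidate_ordering(self, rough_bk, rng):
        cost = CostModel("inverse_power")
        D = np.sort(rng.uniform(0.05, 1.0, 8))
        budget = 0.5 * sum(1.0 / D)
        sol1 = optimal_design(DesignProblem(D, rough_bk, cost, budget))
        perm = rng.permutation(8)
        sol2 = optimal_design(DesignProblem(D[perm], rough_bk, cost, budget))
        np.testing.assert_allclose(np.sort(sol1.X[:, 0]),
                                   np.sort(sol2.X[:, 0]))

    def test_infeasible_budget(self, rough_bk):
        D = np.array([0.1, 0.2])
        with pytest.raises(DesignInfeasibleError):
            optimal_design(DesignProblem(D, rough_bk,
                                         CostModel("inverse_power"), 1.0))

    def test_iterative_prefix_shortcut(self, rough_bk):
        # cumulative iteration cost: the optimum is the longest affordable
        # prefix of the iteration sequence
        D = np.array([1.0, 0.5, 0.25, 0.125, 0.0625])
        cost = CostModel("inverse_power", cumulative_iterative=True)
        sol = optimal_design(DesignProblem(D, rough_bk, cost, budget=9.0))
        np.testing.assert_allclose(np.sort(sol.X[:, 0]),
                                   [0.125, 0.25, 0.5, 1.0])
        assert sol.total_cost == pytest.approx(8.0)

    def test_budget_respected(self, rough_bk, rng):
        cost = CostModel("inverse_power")
        D = np.sort(rng.uniform(0.05, 1.0, 9))
        budget = 0.4 * sum(1.0 / D)
        for mode in ("exhaustive", "greedy"):
            sol = optimal_design(DesignProblem(D, rough_bk, cost, budget),
                                 mode)
            assert sol.total_cost <= budget * (1 + 1e-9)


class TestTheoryUtilities:
    @pytest.mark.parametrize("d, expected", [(1, 2), (2, 12), (3, 78)])
    def test_gamma_d(self, d, expected):
        assert gamma_d(d) == expected

    def test_gamma_d_validation(self):
        with pytest.raises(ValueError):
            gamma_d(0)

    def test_box_fill_distance_1d(self):
        dom = (0.0, 1.0)
        assert box_fill_distance(np.array([0.5]), dom) == pytest.approx(0.5)
        assert box_fill_distance(np.array([0.2, 0.4, 0.6, 0.8, 1.0]),
                                 dom) == pytest.approx(0.2)
        assert box_fill_distance(np.array([]), dom) == pytest.approx(1.0)

    def test_box_fill_distance_2d(self):
        dom = (np.zeros(2), np.ones(2))
        rho = box_fill_distance(np.array([[0.5, 0.5]]), dom)
        assert rho == pytest.approx(0.5, abs=1e-5)

    def test_fill_distance_condition_report(self):
        X = np.linspace(1e-3, 1.0, 400)
        rep = fill_distance_condition(X, (0.0, 1.0), r=2, s=2)
        assert rep.threshold == pytest.approx(1.0 / (2 * 6))
        assert rep.satisfied == (rep.rho <= rep.threshold)
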