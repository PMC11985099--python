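"""Cost-constrained experimental design and design-theory utilities.

With the prior scale fixed, the GRE posterior variance at the continuum limit
is sigma^2 / (1' K_b^{-1} 1), so choosing which simulations to run amounts to

    argmax_{X subset D}  1' K_b^{-1} 1   subject to  sum_{x in X} c(x) <= C,

over a finite candidate set D of affordable fidelities with cost model c and
total budget C.  Both the size of the design and its members are free; the
objective is monotone under set inclusion (adding an experiment never hurts),
so designs saturate to the full candidate set once the budget allows.

Search is brute-force over subsets (hard cap |D| <= 25, with automatic
fallback to greedy forward selection beyond it).  For iterative methods whose
intermediate iterates come for free, the optimum is simply the longest
affordable prefix of the iteration sequence, which is special-cased.

The module also carries the design-theory utilities used for diagnostics:
the dimension constants gamma_d (gamma_1 = 2, gamma_d = 2d(1 + gamma_{d-1}))
and the *box fill distance* — the largest side length of an axis-aligned
empty box in the domain avoiding every design point — together with the
sufficient-condition reporter rho <= 1/(gamma_d (r + 2s)) under which the
higher-order convergence guarantee applies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConditioningError, DesignInfeasibleError
from .linalg import JitteredCholesky

__all__ = [
    "CostModel",
    "DesignProblem",
    "DesignSolution",
    "design_objective",
    "optimal_design",
    "gamma_d",
    "box_fill_distance",
    "fill_distance_condition",
]

_EXHAUSTIVE_CAP = 25
_TIE_RTOL = 1e-12


@dataclass
class CostModel:
    """Simulation cost c(x).

    ``inverse_power`` evaluates sum_i a_i x_i^{-p_i} (the d = 1 default
    a = p = 1 gives c(x) = 1/x, i.e. cost inversely proportional to the step
    size); ``tabulated`` looks costs up in a point -> cost map.  Set
    ``cumulative_iterative`` for iterative methods where reaching x_n yields
    all earlier iterates at no extra cost.
    """

    form: str = "inverse_power"
    exponents: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    scale: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    table: dict | None = None
    cumulative_iterative: bool = False

    def __post_init__(self):
        self.exponents = np.atleast_1d(np.asarray(self.exponents, dtype=float))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=float))
        if self.form == "inverse_power":
            if np.any(self.exponents <= 0) or np.any(self.scale <= 0):
                raise ValueError("inverse_power exponents and scales must be positive")
        elif self.form == "tabulated":
            if not self.table:
                raise ValueError("tabulated cost model requires a table")
            if any(c <= 0 for c in self.table.values()):
                raise ValueError("tabulated costs must be positive")
        else:
            raise ValueError(f"unknown cost form {self.form!r}")

    def __call__(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.form == "tabulated":
            key = tuple(x.tolist()) if x.size > 1 else float(x[0])
            if key not in self.table:
                raise KeyError(f"no tabulated cost for point {key}")
            return float(self.table[key])
        return float(np.sum(self.scale * x ** (-self.exponents)))


@dataclass
class DesignProblem:
    candidates: np.ndarray
    bk: object  # BoundKernel
    cost: CostModel
    budget: float

    def __post_init__(self):
        D = np.asarray(self.candidates, dtype=float)
        if D.ndim == 1:
            D = D.reshape(-1, 1)
        if len({tuple(r) for r in D}) != D.shape[0]:
            raise ValueError("candidate points must be distinct")
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        self.candidates = D
        self.candidate_costs = np.array([self.cost(x) for x in D])
        self.feasible_mask = self.candidate_costs <= self.budget

    @property
    def feasible_candidates(self):
        return self.candidates[self.feasible_mask]


@dataclass
class DesignSolution:
    X: np.ndarray
    objective: float
    total_cost: float
    search_mode: str
    optimality_flag: bool


def design_objective(X, bk):
    """1' K_b^{-1} 1 on the subset X: inverse GRE posterior variance (unit scale)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.shape[0] == 0:
        raise ValueError("design must be non-empty")
    K = bk.gram(X)
    chol = JitteredCholesky(K, X=X)
    ones = np.ones(X.shape[0])
    return float(ones @ chol.solve(ones))


def _subset_key(idx):
    return tuple(sorted(idx))


def _exhaustive(problem, bk):
    D = problem.feasible_candidates
    costs = problem.candidate_costs[problem.feasible_mask]
    m = D.shape[0]
    best = None  # (objective, total_cost, key, X)
    for size in range(1, m + 1):
        for idx in itertools.combinations(range(m), size):
            total = float(costs[list(idx)].sum())
            if total > problem.budget * (1.0 + 1e-12) + 1e-12:
                continue
            X = D[list(idx)]
            try:
                obj = design_objective(X, bk)
            except ConditioningError:
                continue
            key = _subset_key(idx)
            if best is None:
                best = (obj, total, key, X)
                continue
            rel = obj - best[0]
            if rel > _TIE_RTOL * max(1.0, abs(best[0])):
                best = (obj, total, key, X)
            elif abs(rel) <= _TIE_RTOL * max(1.0, abs(best[0])):
                # tie: prefer lower cost, then lexicographically smaller subset
                if (total, key) < (best[1], best[2]):
                    best = (obj, total, key, X)
    return best


def _greedy(problem, bk):
    D = problem.feasible_candidates
    costs = problem.candidate_costs[problem.feasible_mask]
    chosen: list[int] = []
    remaining = set(range(D.shape[0]))
    spent = 0.0
    current_obj = 0.0
    while True:
        best_gain, best_i, best_obj = 0.0, None, None
        for i in sorted(remaining):
            if spent + costs[i] > problem.budget * (1.0 + 1e-12) + 1e-12:
                continue
            trial = D[chosen + [i]]
            try:
                obj = design_objective(trial, bk)
            except ConditioningError:
                continue
            gain = obj - current_obj
            if best_i is None or gain > best_gain:
                best_gain, best_i, best_obj = gain, i, obj
        if best_i is None:
            break
        chosen.append(best_i)
        remaining.discard(best_i)
        spent += costs[best_i]
        current_obj = best_obj
    if not chosen:
        return None
    return current_obj, spent, _subset_key(chosen), D[sorted(chosen)]


def _iterative_prefix(problem, bk):
    """Shortcut for iterative methods: with cumulative iteration costs the
    optimum is simply to run as many iterations as the budget allows."""
    D = problem.candidates
    order = np.argsort(-np.linalg.norm(D, axis=1))  # lo-fi (large x) first
    costs = problem.candidate_costs[order]
    affordable = np.where(costs <= problem.budget)[0]
    if affordable.size == 0:
        raise DesignInfeasibleError("budget below the cost of the first iterate")
    k = int(affordable.max())
    idx = order[: k + 1]
    X = D[idx]
    obj = design_objective(X, bk)
    total = float(costs[k])  # cost of the deepest iterate covers the prefix
    return DesignSolution(X, obj, total, "iterative_prefix", True)


def optimal_design(problem: DesignProblem, mode="exhaustive") -> DesignSolution:
    """Solve the budgeted subset-selection problem over the candidate set."""
    bk = problem.bk
    if problem.cost.cumulative_iterative:
        return _iterative_prefix(problem, bk)
    if not np.any(problem.feasible_mask):
        raise DesignInfeasibleError(
            "no individually affordable candidate within the budget"
        )
    n_feasible = int(problem.feasible_mask.sum())
    if mode == "exhaustive" and n_feasible > _EXHAUSTIVE_CAP:
        warnings.warn(
            f"{n_feasible} feasible candidates exceed the exhaustive cap "
            f"({_EXHAUSTIVE_CAP}); falling back to greedy search",
            stacklevel=2,
        )
        mode = "greedy"
    if mode == "exhaustive":
        best = _exhaustive(problem, bk)
        optimal = True
    elif mode == "greedy":
        best = _greedy(problem, bk)
        optimal = False
    else:
        raise ValueError(f"unknown search mode {mode!r}")
    if best is None:
        raise DesignInfeasibleError("no feasible subset could be evaluated")
    obj, total, _, X = best
    return DesignSolution(X, obj, total, mode, optimal)


def gamma_d(d):
    """Dimension constants gamma_1 = 2, gamma_d = 2d(1 + gamma_{d-1})."""
    if d < 1 or int(d) != d:
        raise ValueError("dimension must be a positive integer")
    g = 2
    for k in range(2, int(d) + 1):
        g = 2 * k * (1 + g)
    return g


def box_fill_distance(X, domain):
    """Largest side length of an axis-aligned empty box avoiding the design.

    ``domain`` is a pair (lo, hi) of vectors (or scalars in d = 1).  Exact in
    d = 1 (largest gap between consecutive points, including the domain
    edges); in d >= 2 computed by bisection over the side length with box
    corners restricted to the grid of design coordinates and the lower domain
    corner, on which the supremum is attained.
    """
    lo, hi = (np.atleast_1d(np.asarray(v, dtype=float)) for v in domain)
    d = lo.shape[0]
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return float(np.max(hi - lo))
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.shape[1] != d:
        raise ValueError("design dimension does not match the domain")
    if np.any(X < lo) or np.any(X > hi):
        raise ValueError("design points must lie inside the domain")
    if d == 1:
        pts = np.sort(X[:, 0])
        edges = np.concatenate([[lo[0]], pts, [hi[0]]])
        return float(np.max(np.diff(edges)))
    # candidate corner grid: design coordinates and the lower domain corner
    axes = [np.unique(np.concatenate([[lo[k]], X[:, k]])) for k in range(d)]

    def empty_box_exists(nu):
        for corner in itertools.product(*axes):
            c = np.asarray(corner)
            if np.any(c + nu > hi + 1e-15):
                continue
            inside = np.all((X > c + 1e-15) & (X < c + nu - 1e-15), axis=1)
            if not np.any(inside):
                return True
        return False

    lo_nu, hi_nu = 0.0, float(np.min(hi - lo))
    if empty_box_exists(hi_nu):
        return hi_nu
    while hi_nu - lo_nu > 1e-6:
        mid = 0.5 * (lo_nu + hi_nu)
        if empty_box_exists(mid):
            lo_nu = mid
        else:
            hi_nu = mid
    return 0.5 * (lo_nu + hi_nu)


@dataclass
class FillDistanceReport:
    rho: float
    threshold: float
    satisfied: bool


def fill_distance_condition(X, domain, r, s, d=None) -> FillDistanceReport:
    """Report whether rho <= 1/(gamma_d (r + 2s)), the sufficient coverage
    condition for the polynomial-acceleration guarantee (diagnostic only)."""
    lo, _ = (np.atleast_1d(np.asarray(v, dtype=float)) for v in domain)
    d = d or lo.shape[0]
    rho = box_fill_distance(X, domain)
    threshold = 1.0 / (gamma_d(d) * (r + 2 * s))
    return FillDistanceReport(rho=rho, threshold=threshold,
                              satisfied=rho <= threshold)
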