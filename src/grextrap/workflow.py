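"""End-to-end multi-fidelity workflow and convergence benchmarking.

The pragmatic three-step workflow for a simulator with d discretization
parameters and a computational budget C:

1. **Probe each axis.**  Simulate along a short schedule of values of x_i
   (five logarithmically spaced points from the lo-fi value down by a factor
   16), with the other components held at the lo-fi setting, and estimate the
   per-axis convergence order r_i, kernel smoothness s_i, length-scale l_i
   and scale sigma_i by quasi-maximum-likelihood grid search.

2. **Assemble and design.**  Posit the conservative additive error bound
   b(x) = sigma_1 x_1^{r_1} + ... + sigma_d x_d^{r_d}, build the tensor
   product base kernel from the per-axis factors, and solve the
   cost-constrained experimental design problem over a candidate grid.

3. **Simulate and extrapolate.**  Run the selected design and return the
   Gauss-Richardson posterior as the approximation to f(0).

:func:`convergence_study` drives the benchmark comparisons: a base design is
scaled by a factor h over a decreasing sequence, the chosen method (GRE or a
classical extrapolation baseline) is applied at every h, and the empirical
convergence order is measured as the least-squares slope of log error against
log h, excluding rows where roundoff dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classical
from .bounds import AdditivePowersBound
from .data import SimulationLog
from .design import CostModel, DesignProblem, optimal_design
from .kernels import BoundKernel, Matern, ProductKernel, make_kernel
from .model import GaussRichardson
from .mp_backend import fit_extended
from .orders import HyperGrid, fit_hyperparameters

__all__ = [
    "WorkflowConfig",
    "WorkflowReport",
    "run_workflow",
    "ConvergenceStudy",
    "convergence_study",
    "fit_loglog_slope",
]


@dataclass
class WorkflowConfig:
    x_lofi: np.ndarray
    budget: float
    candidates: np.ndarray
    grid: HyperGrid = field(default_factory=HyperGrid)
    kernel_family: str = "matern"
    probe_points: int = 5
    probe_decay: float = 16.0
    design_mode: str = "exhaustive"

    def __post_init__(self):
        self.x_lofi = np.atleast_1d(np.asarray(self.x_lofi, dtype=float))
        C = np.asarray(self.candidates, dtype=float)
        if C.ndim == 1:
            C = C.reshape(-1, 1)
        self.candidates = C


@dataclass
class WorkflowReport:
    hyperfits: list
    bound: AdditivePowersBound
    kernel: object
    design: object
    results: object
    estimate: float
    error: float | None = None


def _probe_schedule(x_lo, n_points, decay):
    return x_lo * np.geomspace(1.0, 1.0 / decay, n_points)


def run_workflow(testbed, config: WorkflowConfig) -> WorkflowReport:
    """Execute probe -> design -> extrapolate on a testbed simulator."""
    d = config.x_lofi.shape[0]
    if d != testbed.d:
        raise ValueError("lo-fi setting dimension does not match the testbed")
    # Step 1: per-axis probes and hyperparameter estimation
    hyperfits = []
    for i in range(d):
        probes = _probe_schedule(config.x_lofi[i], config.probe_points,
                                 config.probe_decay)
        X = np.tile(config.x_lofi, (config.probe_points, 1))
        X[:, i] = probes
        y = np.array([testbed.evaluator(x if d > 1 else float(x[0]))
                      for x in X])
        probe_log = SimulationLog(probes.reshape(-1, 1), y,
                                  meta={"axis": i})
        hyperfits.append(
            fit_hyperparameters(probe_log, config.grid,
                                bound_form="monomial_1d",
                                kernel_family=config.kernel_family)
        )
    # Step 2: additive bound, tensor kernel, experimental design
    orders = np.array([hf.r_hat for hf in hyperfits])
    weights = np.array([max(hf.sigma_hat, 1e-12) for hf in hyperfits])
    bound = AdditivePowersBound(orders, weights)
    factors = [
        make_kernel(config.kernel_family, smoothness=hf.s_hat,
                    lengthscales=hf.l_hat, d=1)
        for hf in hyperfits
    ]
    kernel = factors[0] if d == 1 else ProductKernel(factors)
    bk = BoundKernel(bound, kernel)
    problem = DesignProblem(config.candidates, bk, testbed.cost, config.budget)
    solution = optimal_design(problem, mode=config.design_mode)
    # Step 3: simulate the design and extrapolate
    final_log = testbed.simulate_log(solution.X)
    results = GaussRichardson(final_log, bk).fit()
    error = (abs(results.mean_at_zero - testbed.truth)
             if testbed.truth is not None else None)
    return WorkflowReport(
        hyperfits=hyperfits,
        bound=bound,
        kernel=kernel,
        design=solution,
        results=results,
        estimate=results.mean_at_zero,
        error=error,
    )


@dataclass
class ConvergenceStudy:
    table: pd.DataFrame
    slope: float | None
    method: str


def fit_loglog_slope(h, err, floor=0.0):
    """Least-squares slope of log|err| vs log h over rows above the roundoff
    floor.  Returns (slope, valid_mask); slope is None with < 2 valid rows."""
    h = np.asarray(h, dtype=float)
    err = np.asarray(err, dtype=float)
    valid = np.isfinite(err) & (err > floor)
    if valid.sum() < 2:
        return None, valid
    coeff = np.polyfit(np.log(h[valid]), np.log(err[valid]), 1)
    return float(coeff[0]), valid


def _classical_estimate(method, xs, ys, n_terms=None):
    order = np.argsort(-xs)  # decreasing fidelity sequence
    xs_s, ys_s = xs[order], ys[order]
    if method == "richardson":
        scheme = classical.richardson(n_terms or len(xs_s))
        return classical.e_algorithm(scheme, xs_s, ys_s, m=0)
    if method == "shanks":
        n = n_terms or 2
        scheme = classical.shanks(n)
        table = classical.extrapolation_table(scheme, xs_s, ys_s)
        finite = table[np.isfinite(table)]
        if finite.size == 0:
            return np.nan
        return float(finite[-1])
    raise ValueError(f"unknown classical method {method!r}")


def convergence_study(
    method,
    testbed,
    base_design,
    h_sequence,
    kernel=None,
    bound=None,
    precision="double",
    dps=50,
    n_terms=None,
):
    """Scaled-design convergence benchmark for GRE or a classical baseline.

    Per h: scale the base design, evaluate the testbed, apply the method, and
    record the absolute error |f(0) - estimate| and (for GRE) the signed
    relative error (f(0) - m(0)) / sd(0).  A log-log slope is fitted over the
    rows not dominated by roundoff.

    ``precision='extended'`` runs the simulator and the GRE solve in mpmath
    arithmetic at ``dps`` digits, allowing the study to follow the error far
    below double-precision roundoff.
    """
    base_design = np.asarray(base_design, dtype=float)
    h_sequence = np.asarray(h_sequence, dtype=float)
    bound = bound or testbed.bound_truth
    if method == "gre" and kernel is None:
        kernel = Matern(2)
    truth = testbed.truth
    rows = []
    for h in h_sequence:
        xs = h * base_design
        if method == "gre":
            if precision == "extended":
                import mpmath

                with mpmath.workdps(dps):
                    xs_mp = [mpmath.mpf(x) for x in xs]
                    ys_mp = [testbed.evaluator_mp(x) for x in xs_mp]
                    res = fit_extended(xs_mp, ys_mp, BoundKernel(bound, kernel),
                                       dps=dps)
                    est_err = abs(mpmath.mpf(truth) - res.mean_at_zero)
                    sd = mpmath.sqrt(res.var_at_zero)
                    rel = ((mpmath.mpf(truth) - res.mean_at_zero) / sd
                           if sd > 0 else mpmath.mpf("nan"))
                    est = float(res.mean_at_zero)
                    abs_err = float(est_err)
                    rel_err = float(rel)
            else:
                log = testbed.simulate_log(xs, with_costs=False)
                res = GaussRichardson(log, BoundKernel(bound, kernel)).fit()
                est = res.mean_at_zero
                abs_err = abs(truth - est)
                sd = math.sqrt(res.var_at_zero)
                rel_err = (truth - est) / sd if sd > 0 else np.nan
        else:
            ys = np.array([testbed.evaluator(x) for x in xs])
            est = _classical_estimate(method, xs, ys, n_terms)
            abs_err = abs(truth - est) if np.isfinite(est) else np.nan
            rel_err = np.nan
        rel_to_truth = abs_err / abs(truth) if truth != 0 else np.nan
        rows.append(dict(h=h, estimate=est, abs_error=abs_err,
                         rel_error=rel_err, rel_to_truth=rel_to_truth))
    table = pd.DataFrame(rows)
    if precision == "extended":
        floor = 10.0 ** (-dps + 10) * max(1.0, abs(truth))
    else:
        floor = 1e-12 * max(1.0, abs(truth))
    slope = None
    if len(table) > 1:
        slope, valid = fit_loglog_slope(table["h"], table["abs_error"], floor)
        table["in_slope_fit"] = valid
    return ConvergenceStudy(table=table, slope=slope, method=method)
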