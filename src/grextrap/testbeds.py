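"""Benchmark problems with known continuum limits.

Three families of testbeds exercise the extrapolation machinery:

* **Central differences** for numerical differentiation: f(x) =
  (psi(t0 + x) - psi(t0 - x)) / (2x) is a second-order approximation to
  psi'(t0).  The test function psi(t) = sin(10 t) + 1_{t>0} t^{s+4} is tuned
  so that the normalized error has exactly s derivatives: a kernel of
  smoothness s is then correctly (and not over-) specified.

* **Trapezoidal quadrature**: the composite trapezoidal value y_n with n
  panels on [0, 1] is attached to the fidelity x_n = 1/n.  By the
  Euler-Maclaurin expansion the error is a smooth function of x_n^2, so GRE
  with b(x) = x^2 and a smoothness-2 kernel plays the role of a GP Romberg
  method.  Only reciprocal fidelities x = 1/n are admissible.

* **A synthetic multi-dimensional simulator** standing in for an expensive
  multi-discretization code: f(x) = f0 + sum_i c_i x_i^{r_i} (1 + g_i(x))
  with known continuum limit f0, known per-dimension convergence orders r_i,
  smooth bounded modulations g_i (low-order trigonometric, seed-determined,
  |g_i| <= 0.3) and an inverse-power cost model.  It is deterministic given
  its seed: there is no observation noise, matching the setting where f is a
  fixed (nonrandom) numerical method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import mpmath
import numpy as np

from .bounds import AdditivePowersBound, MonomialBound
from .data import SimulationLog
from .design import CostModel

__all__ = [
    "Testbed",
    "central_difference_problem",
    "trapezoid_problem",
    "sequence_to_design",
    "synthetic_md_simulator",
]


@dataclass
class Testbed:
    name: str
    truth: float
    evaluator: Callable
    bound_truth: object
    cost: CostModel
    d: int = 1
    evaluator_mp: Callable | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def simulate_log(self, X, with_costs=True) -> SimulationLog:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.array([self.evaluator(x if self.d > 1 else float(x[0]))
                      for x in X])
        costs = np.array([self.cost(x) for x in X]) if with_costs else None
        return SimulationLog(X, y, costs, meta={"testbed": self.name})


def central_difference_problem(s=2, t0=0.0) -> Testbed:
    """Numerical differentiation of psi(t) = sin(10 t) + 1_{t>0} t^{s+4}.

    The evaluator is the central difference (psi(t0+x) - psi(t0-x))/(2x); the
    continuum limit is psi'(t0) (equal to 10 at t0 = 0).  The true error
    bound is b(x) = x^2 and the normalized error is exactly s-smooth.
    """
    if s < 0 or int(s) != s:
        raise ValueError("smoothness s must be a nonnegative integer")
    s = int(s)

    def psi(t):
        return np.sin(10.0 * t) + (t ** (s + 4) if t > 0 else 0.0)

    def evaluator(x):
        x = float(x)
        if x <= 0:
            raise ValueError("central differences require x > 0")
        return (psi(t0 + x) - psi(t0 - x)) / (2.0 * x)

    def psi_mp(t):
        out = mpmath.sin(10 * t)
        if t > 0:
            out += t ** (s + 4)
        return out

    def evaluator_mp(x):
        x = mpmath.mpf(x) if not isinstance(x, mpmath.mpf) else x
        if x <= 0:
            raise ValueError("central differences require x > 0")
        t = mpmath.mpf(t0)
        return (psi_mp(t + x) - psi_mp(t - x)) / (2 * x)

    truth = 10.0 * np.cos(10.0 * t0) + ((s + 4) * t0 ** (s + 3) if t0 > 0 else 0.0)
    return Testbed(
        name="central_difference",
        truth=float(truth),
        evaluator=evaluator,
        bound_truth=MonomialBound(2),
        cost=CostModel("inverse_power"),
        evaluator_mp=evaluator_mp,
        meta={"s": s, "t0": t0},
    )


_TRAPZ_TRUTH = (1.0 - np.cos(10.0)) / 10.0 + 1.0 / 3.0  # int_0^1 sin(10t)+t^2 dt


def _panels_from_x(x, tol=1e-9):
    n = round(1.0 / float(x))
    if n < 1 or abs(1.0 / n - float(x)) > tol * max(1.0, float(x)):
        raise ValueError(
            f"x={x} is not an admissible trapezoid fidelity (must equal 1/n)"
        )
    return n


def trapezoid_problem() -> Testbed:
    """Composite trapezoidal integration of psi(t) = sin(10 t) + t^2 on [0, 1].

    Fidelity x = 1/n maps to the n-panel trapezoidal value; the continuum
    limit is the integral (1 - cos 10)/10 + 1/3, the error bound b(x) = x^2.
    """

    def evaluator(x):
        n = _panels_from_x(x)
        t = np.linspace(0.0, 1.0, n + 1)
        vals = np.sin(10.0 * t) + t**2
        return float(np.trapezoid(vals, t))

    def evaluator_mp(x):
        n = _panels_from_x(float(x))
        hstep = mpmath.mpf(1) / n
        total = (mpmath.sin(0) + 0 + mpmath.sin(10) + 1) / 2
        for k in range(1, n):
            t = k * hstep
            total += mpmath.sin(10 * t) + t**2
        return total * hstep

    return Testbed(
        name="trapezoid",
        truth=float(_TRAPZ_TRUTH),
        evaluator=evaluator,
        bound_truth=MonomialBound(2),
        cost=CostModel("inverse_power"),
        evaluator_mp=evaluator_mp,
    )


def sequence_to_design(rule="reciprocal", n=5, lam=2.0):
    """Design points for iterative-sequence adapters: x_k = 1/k or lam^{-k}.

    The geometric rule starts at 1 (so lam = 2, n = 5 yields the dyadic
    design {1, 1/2, 1/4, 1/8, 1/16}).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if rule == "reciprocal":
        return np.array([1.0 / k for k in range(1, n + 1)])
    if rule == "geometric":
        if lam <= 1:
            raise ValueError("geometric rule requires lam > 1")
        return np.array([lam ** (-k) for k in range(n)])
    raise ValueError(f"unknown design rule {rule!r}")


def synthetic_md_simulator(d, r_true, f0=1.0, cost=None, seed=0,
                           noise_amp=0.3) -> Testbed:
    """Deterministic multi-fidelity simulator with known limit and orders.

    f(x) = f0 + sum_i c_i x_i^{r_i} (1 + g_i(x_i)) with coefficients
    c_i in [0.5, 2] and smooth separable modulations
    g_i(x_i) = a_i sin(w_i x_i + phi_i), |a_i| <= noise_amp, all drawn once
    from the seed.  Separability keeps the simulator consistent with the
    additive error bound the workflow posits, so that per-axis convergence
    orders are well defined.  The default cost model is c(x) = sum_i x_i^{-1}.
    """
    if d not in (1, 2, 3):
        raise ValueError("synthetic simulator supports d in {1, 2, 3}")
    r_true = np.atleast_1d(np.asarray(r_true, dtype=float))
    if r_true.shape[0] != d:
        raise ValueError("r_true must have length d")
    if np.any(r_true <= 0):
        raise ValueError("true convergence orders must be positive")
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(0.5, 2.0, size=d)
    amps = rng.uniform(0.5, 1.0, size=d) * noise_amp
    omegas = rng.uniform(0.5, 2.0, size=d)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=d)

    def evaluator(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.shape[0] != d:
            raise ValueError(f"point has dimension {x.shape[0]}, expected {d}")
        g = amps * np.sin(omegas * x + phases)
        return float(f0 + np.sum(coeffs * x**r_true * (1.0 + g)))

    cost = cost or CostModel("inverse_power", exponents=np.ones(d),
                             scale=np.ones(d))
    return Testbed(
        name="synthetic_md",
        truth=float(f0),
        evaluator=evaluator,
        bound_truth=AdditivePowersBound(r_true),
        cost=cost,
        d=d,
        seed=seed,
        meta={"coeffs": coeffs, "r_true": r_true, "noise_amp": noise_amp},
    )
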