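"""Gauss-Richardson extrapolation: the scalar model and its results object.

The prior places a Gaussian process on the simulator output,

    f ~ GP(0, sigma^2 [k0^2 + b(x) b(x') k_e(x, x')]),

where b encodes the numerical method's error bound and k_e the smoothness of
the normalized error (f(x) - f(0))/b(x).  Taking the objective (flat) prior
limit k0 -> infinity on the unknown continuum value f(0) and conditioning on
the simulation log yields the shift-invariant formulas implemented here: with
K_b the Gram matrix of k_b on the design and 1 the all-ones vector,

    m_n[f](0)   = (1' K_b^{-1} y) / (1' K_b^{-1} 1),
    k_n[f](0,0) = sigma_n^2[f] / (1' K_b^{-1} 1),
    sigma_n^2[f] = (1/n) [ y' K_b^{-1} y - (1' K_b^{-1} y)^2 / (1' K_b^{-1} 1) ],

the scale estimator being the squared RKHS *semi*-norm of the conditional
mean divided by n, which prevents asymptotic over-confidence of the credible
intervals.  The conditional mean interpolates the data and the point estimate
at 0 is an affine combination of the observations with weights summing to 1.

Usage is statsmodels-like::

    model = GaussRichardson(log, BoundKernel(MonomialBound(2), Matern(2)))
    res = model.fit()
    res.mean_at_zero, res.credible_interval(0.05), res.summary()
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import SimulationLog
from .kernels import BoundKernel
from .linalg import JitteredCholesky

__all__ = [
    "GaussRichardson",
    "GREResults",
    "CredibleInterval",
    "fit",
    "scale_estimator",
]


@dataclass
class CredibleInterval:
    level: float
    lower: float
    upper: float

    @property
    def width(self):
        return self.upper - self.lower


class GaussRichardson:
    """Model object tying a simulation log to a bound-weighted prior kernel.

    Parameters
    ----------
    log : SimulationLog
        Distinct fidelities x_i in (0, inf)^d with outputs f(x_i).
    bound_kernel : BoundKernel
        Prior covariance k_b(x, x') = b(x) b(x') k_e(x, x').
    """

    def __init__(self, log: SimulationLog, bound_kernel: BoundKernel):
        self.log = log
        self.bk = bound_kernel

    @classmethod
    def from_dataframe(cls, df, bound, kernel):
        return cls(SimulationLog.from_dataframe(df), BoundKernel(bound, kernel))

    def fit(self) -> "GREResults":
        log = self.log
        K = self.bk.gram(log.X)
        chol = JitteredCholesky(K, X=log.X)
        ones = np.ones(log.n)
        w = chol.solve(ones)  # K^{-1} 1
        v = chol.solve(log.y)  # K^{-1} y
        a = float(ones @ w)
        sy = float(ones @ v)
        mean0 = sy / a
        quad = float(log.y @ v) - sy**2 / a
        sigma2 = max(quad / log.n, 0.0)
        var0 = sigma2 / a
        return GREResults(
            model=self,
            mean_at_zero=mean0,
            var_at_zero=var0,
            sigma2=sigma2,
            _chol=chol,
            _w=w,
            _a=a,
            _alpha=v - mean0 * w,
        )


class GREResults:
    """Fitted posterior: point estimate, calibrated scale, and predictions."""

    def __init__(self, model, mean_at_zero, var_at_zero, sigma2, _chol, _w, _a, _alpha):
        self.model = model
        self.mean_at_zero = float(mean_at_zero)
        self.var_at_zero = float(var_at_zero)
        self.sigma2 = float(sigma2)
        self._chol = _chol
        self._w = _w
        self._a = _a
        self._alpha = _alpha

    @property
    def log(self):
        return self.model.log

    @property
    def bk(self):
        return self.model.bk

    def predict(self, x):
        """Conditional mean and variance at a point x in the domain box.

        A point with b(x) = 0 (in particular x = 0) carries no covariance
        with the data through k_b and is handled by the closed-form limit
        values at the origin.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.bk.bound(x) == 0.0:
            return self.mean_at_zero, self.var_at_zero
        kvec = self.bk(self.log.X, x.reshape(1, -1))[:, 0]
        kxx = float(self.bk(x.reshape(1, -1))[0, 0])
        mean = self.mean_at_zero + float(kvec @ self._alpha)
        u = self._chol.solve(kvec)
        var = self.sigma2 * (
            kxx - float(kvec @ u) + (float(kvec @ self._w) - 1.0) ** 2 / self._a
        )
        return mean, max(var, 0.0)

    def predict_many(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        out = np.array([self.predict(x) for x in X])
        return out[:, 0], out[:, 1]

    def credible_interval(self, alpha=0.05) -> CredibleInterval:
        """Central 100(1-alpha)% Gaussian credible interval for f(0)."""
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        half = norm.ppf(1.0 - alpha / 2.0) * math.sqrt(self.var_at_zero)
        return CredibleInterval(
            level=1.0 - alpha,
            lower=self.mean_at_zero - half,
            upper=self.mean_at_zero + half,
        )

    def summary(self, alpha=0.05):
        ci = self.credible_interval(alpha)
        lines = [
            "Gauss-Richardson Extrapolation Results",
            "=" * 46,
            f"{'No. simulations:':<28}{self.log.n}",
            f"{'Fidelity dimension:':<28}{self.log.d}",
            f"{'Bound:':<28}{self.bk.bound!r}",
            f"{'Base kernel:':<28}{type(self.bk.base).__name__}"
            f"(s={self.bk.base.smoothness})",
            "-" * 46,
            f"{'Estimate of f(0):':<28}{self.mean_at_zero:.10g}",
            f"{'Posterior sd at 0:':<28}{math.sqrt(self.var_at_zero):.6g}",
            f"{'Scale sigma_n^2:':<28}{self.sigma2:.6g}",
            f"{f'{100 * (1 - alpha):.0f}% credible interval:':<28}"
            f"[{ci.lower:.10g}, {ci.upper:.10g}]",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_json(self, alpha=0.05):
        ci = self.credible_interval(alpha)
        return json.dumps(
            dict(
                mean_at_zero=self.mean_at_zero,
                var_at_zero=self.var_at_zero,
                sigma2=self.sigma2,
                n=self.log.n,
                d=self.log.d,
                alpha=alpha,
                interval=[ci.lower, ci.upper],
            )
        )

    def plot(self, ax=None, grid=200, alpha=0.05):
        """Plot data, posterior mean and credible band over [0, max x] (d=1)."""
        if self.log.d != 1:
            raise ValueError("plotting is implemented for d = 1 only")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(0.0, float(self.log.X.max()), grid)
        mean, var = self.predict_many(xs)
        sd = np.sqrt(var)
        z = norm.ppf(1.0 - alpha / 2.0)
        ax.plot(xs, mean, label="posterior mean")
        ax.fill_between(xs, mean - z * sd, mean + z * sd, alpha=0.25,
                        label=f"{100 * (1 - alpha):.0f}% band")
        ax.plot(self.log.X[:, 0], self.log.y, "o", label="simulations")
        ax.errorbar([0.0], [self.mean_at_zero],
                    yerr=[z * math.sqrt(self.var_at_zero)], fmt="*", capsize=4,
                    label="extrapolation at 0")
        ax.set_xlabel("discretization parameter x")
        ax.set_ylabel("f(x)")
        ax.legend()
        return ax


def fit(log, bound_kernel) -> GREResults:
    """Functional entry point: fit the GRE posterior to a simulation log."""
    return GaussRichardson(log, bound_kernel).fit()


def scale_estimator(log, bound_kernel) -> float:
    """The RKHS semi-norm scale estimator sigma_n^2[f] (nonnegative)."""
    return fit(log, bound_kernel).sigma2
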