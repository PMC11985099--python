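"""Extended-precision backend for convergence studies.

Double precision limits how far the dyadic scaling h -> 0 can be pushed in a
convergence study: both the simulator evaluations (cancellation) and the
ill-conditioned kernel solves eventually drown the signal in roundoff.  This
module mirrors the scalar Gauss-Richardson fit in mpmath arbitrary-precision
arithmetic so that empirical acceleration orders can be measured over a wide
range of h, at the cost of speed.  It is only practical for the small designs
(n ~ 5) used in the benchmark problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import mpmath
import numpy as np

__all__ = ["fit_extended", "ExtendedFit"]


@dataclass
class ExtendedFit:
    mean_at_zero: object  # mpmath.mpf
    var_at_zero: object
    sigma2: object
    dps: int

    def as_floats(self):
        return (
            float(self.mean_at_zero),
            float(self.var_at_zero),
            float(self.sigma2),
        )


def fit_extended(X, y, bound_kernel, dps=50):
    """Scalar GRE fit in mpmath arithmetic at ``dps`` decimal digits.

    ``X`` is a sequence of points (floats or mpf, d = 1 or sequences of
    length d); ``y`` a sequence of outputs, ideally already computed at
    extended precision by an mpmath-aware evaluator.
    """
    with mpmath.workdps(dps):
        pts = [x if np.ndim(x) else [x] for x in X]
        n = len(pts)
        K = mpmath.matrix(n, n)
        for i in range(n):
            for j in range(i, n):
                val = bound_kernel.eval_one(pts[i], pts[j])
                K[i, j] = val
                K[j, i] = val
        ones = mpmath.matrix([1] * n)
        yv = mpmath.matrix([mpmath.mpf(v) if isinstance(v, float) else v for v in y])
        w = mpmath.lu_solve(K, ones)
        v = mpmath.lu_solve(K, yv)
        a = sum(w[i] for i in range(n))
        sy = sum(v[i] for i in range(n))
        mean0 = sy / a
        quad = sum(yv[i] * v[i] for i in range(n)) - sy**2 / a
        sigma2 = quad / n
        if sigma2 < 0:
            sigma2 = mpmath.mpf(0)
        return ExtendedFit(mean0, sigma2 / a, sigma2, dps)
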