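"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's improper-limit code path: the proper
conjugate-GP posterior with a finite prior scale k0 on f(0) is assembled
densely and solved in mpmath extended precision, so it remains accurate for
the very large k0 values (up to 1e8) needed to probe the k0 -> infinity
limit.
"""

import mpmath
import numpy as np


def finite_k0_posterior(X, y, bound_kernel, k0, x, dps=50):
    """Zero-mean conjugate GP with prior covariance k0^2 + k_b(x, x').

    Returns (mean, var) at the point x with unit overall scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != np.atleast_1d(x).shape[0]:
        X = X.reshape(len(y), -1)
    with mpmath.workdps(dps):
        k0 = mpmath.mpf(k0)
        n = X.shape[0]
        pts = [list(row) for row in X]
        xq = list(np.atleast_1d(np.asarray(x, dtype=float)))
        K = mpmath.matrix(n, n)
        for i in range(n):
            for j in range(n):
                K[i, j] = k0**2 + bound_kernel.eval_one(pts[i], pts[j])
        kvec = mpmath.matrix(
            [k0**2 + bound_kernel.eval_one(pts[i], xq) for i in range(n)]
        )
        yv = mpmath.matrix([mpmath.mpf(v) for v in y])
        alpha = mpmath.lu_solve(K, yv)
        mean = sum(kvec[i] * alpha[i] for i in range(n))
        beta = mpmath.lu_solve(K, kvec)
        prior_var = k0**2 + bound_kernel.eval_one(xq, xq)
        var = prior_var - sum(kvec[i] * beta[i] for i in range(n))
        return float(mean), float(var)


def determinant_ratio(scheme, xs, ys, m=0):
    """Direct determinant-ratio evaluation of the extrapolation estimator,
    using numpy determinants on explicitly assembled matrices."""
    n = scheme.n_terms
    cols = range(m, m + n)
    G = np.array(
        [[scheme.basis(i, j, xs, ys) for j in cols] for i in range(1, n)]
    )
    vals = np.array([ys[j] for j in cols])
    num = np.vstack([vals, G])
    den = np.vstack([np.ones(n), G])
    return float(np.linalg.det(num) / np.linalg.det(den))
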