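"""Shared linear-algebra helpers: jittered Cholesky factorization.

Gram matrices of smooth kernels on clustered designs are often numerically
singular; all solves in the package go through a symmetric factorization with
adaptive diagonal jitter, starting at 1e-12 * trace(K)/n and escalating by
factors of 10 at most six times before raising a :class:`ConditioningError`
that names the closest pair of design points.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import ConditioningError

__all__ = ["JitteredCholesky"]

_BASE_JITTER = 1e-12
_MAX_ESCALATIONS = 6


def _closest_pair(X):
    n = X.shape[0]
    best, pair = np.inf, None
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(X[i] - X[j]))
            if dist < best:
                best, pair = dist, (i, j)
    return pair, best


class JitteredCholesky:
    """Cholesky factorization of K + jitter*I with adaptive escalation."""

    def __init__(self, K, X=None):
        K = np.asarray(K, dtype=float)
        n = K.shape[0]
        scale = max(np.trace(K) / n, np.finfo(float).tiny)
        self.jitter = 0.0
        factor = None
        try:
            factor = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            pass
        if factor is None:
            jitter = _BASE_JITTER * scale
            for _ in range(_MAX_ESCALATIONS):
                try:
                    factor = cho_factor(K + jitter * np.eye(n), lower=True)
                    self.jitter = jitter
                    break
                except np.linalg.LinAlgError:
                    jitter *= 10.0
        if factor is None:
            msg = "Gram matrix not positive definite within the jitter budget"
            pair = None
            if X is not None and n > 1:
                pair, dist = _closest_pair(np.asarray(X, dtype=float))
                msg += (
                    f"; nearest design points are rows {pair[0]} and {pair[1]}"
                    f" (distance {dist:.3e})"
                )
            raise ConditioningError(msg, offending_pair=pair)
        self._factor = factor
        self.n = n

    def solve(self, b):
        return cho_solve(self._factor, np.asarray(b, dtype=float))

    @property
    def logdet(self):
        # logdet of the jittered matrix actually factorized
        return 2.0 * float(np.sum(np.log(np.diag(self._factor[0]))))
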