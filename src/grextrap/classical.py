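"""Classical convergence-acceleration baselines via the E-algorithm.

The E-algorithm unifies the classical extrapolation methods.  Given a
convergent sequence of numerical approximations f(x_m) it posits

    f(x_m) = f(0) + a_1 g_1(m) + ... + a_{n-1} g_{n-1}(m)

for known basis functions g_i and unknown coefficients a_i, instantiates the
ansatz at n consecutive indices m, ..., m+n-1, and solves the linear system
for the limit f(0).  The solution can equivalently be written as a ratio of
two n x n determinants; both routes are implemented, with the linear-solve
route the default for stability.

Different basis choices recover the classical schemes:

* Richardson:      g_i(m) = x_m^i          (polynomial extrapolation to 0)
* Shanks:          g_i(m) = f(x_{m+i}) - f(x_{m+i-1})
* Germain-Bonne:   g_i(m) = (f(x_{m+1}) - f(x_m))^i
* Thiele:          g_i(m) = x_m^i and g_{i+p}(m) = f(x_m) x_m^i, n = 2p+1
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import DegenerateSchemeError

__all__ = [
    "ExtrapolationScheme",
    "richardson",
    "shanks",
    "germain_bonne",
    "thiele",
    "custom_scheme",
    "e_algorithm",
    "extrapolation_table",
]

_COND_LIMIT = 1e14


@dataclass
class ExtrapolationScheme:
    """A basis family g_i(m) for the E-algorithm.

    ``basis(i, m, xs, ys)`` returns g_i(m); ``lookahead`` is how many sequence
    values beyond the n-point window the basis consults (0 for Richardson,
    n-1 for Shanks, 1 for Germain-Bonne).
    """

    name: str
    n_terms: int
    basis: Callable[[int, int, np.ndarray, np.ndarray], float]
    lookahead: int = 0

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("an extrapolation scheme needs n_terms >= 2")


def richardson(n_terms):
    """Polynomial extrapolation to the origin on n_terms consecutive values."""
    return ExtrapolationScheme(
        "richardson", n_terms, lambda i, m, xs, ys: xs[m] ** i, lookahead=0
    )


def shanks(n_terms=2):
    """Shanks' transformation; exact on geometric error decay."""
    return ExtrapolationScheme(
        "shanks",
        n_terms,
        lambda i, m, xs, ys: ys[m + i] - ys[m + i - 1],
        lookahead=n_terms - 1,
    )


def germain_bonne(n_terms):
    return ExtrapolationScheme(
        "germain_bonne",
        n_terms,
        lambda i, m, xs, ys: (ys[m + 1] - ys[m]) ** i,
        lookahead=1,
    )


def thiele(p):
    """Rational extrapolation with numerator/denominator degree p (n = 2p+1)."""

    def basis(i, m, xs, ys):
        if i <= p:
            return xs[m] ** i
        return ys[m] * xs[m] ** (i - p)

    return ExtrapolationScheme("thiele", 2 * p + 1, basis, lookahead=0)


def custom_scheme(n_terms, basis, lookahead=0, name="custom"):
    return ExtrapolationScheme(name, n_terms, basis, lookahead)


def _window_matrices(scheme, xs, ys, m):
    n = scheme.n_terms
    if m < 0:
        raise ValueError("start index must be nonnegative")
    if m + n - 1 + scheme.lookahead >= len(ys) or m + n - 1 >= len(xs):
        raise ValueError(
            f"sequence too short for n={n} entries from m={m} "
            f"(lookahead {scheme.lookahead})"
        )
    cols = range(m, m + n)
    G = np.array(
        [[scheme.basis(i, j, xs, ys) for j in cols] for i in range(1, n)],
        dtype=float,
    ).reshape(n - 1, n)
    vals = np.asarray([ys[j] for j in cols], dtype=float)
    return vals, G


def e_algorithm(scheme, xs, ys, m=0, method="solve"):
    """The estimator S_m: extrapolate n consecutive values starting at m.

    ``method='solve'`` solves the instantiated ansatz as a linear system
    (stable); ``method='det'`` evaluates the determinant-ratio form directly.
    Both raise :class:`DegenerateSchemeError` when the scheme degenerates
    (vanishing denominator determinant / singular system).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    vals, G = _window_matrices(scheme, xs, ys, m)
    n = scheme.n_terms
    if method == "det":
        num = np.vstack([vals, G])
        den = np.vstack([np.ones(n), G])
        den_det = np.linalg.det(den)
        if den_det == 0.0 or not np.isfinite(den_det):
            raise DegenerateSchemeError(
                f"{scheme.name}: denominator determinant vanishes at m={m}"
            )
        return float(np.linalg.det(num) / den_det)
    # linear-solve route: unknowns (f0, a_1..a_{n-1});
    # row j:  f0 + sum_i a_i g_i(m+j) = f(x_{m+j})
    A = np.column_stack([np.ones(n), G.T])
    if np.linalg.cond(A) > _COND_LIMIT:
        raise DegenerateSchemeError(
            f"{scheme.name}: degenerate (near-singular) system at m={m}"
        )
    try:
        sol = np.linalg.solve(A, vals)
    except np.linalg.LinAlgError as err:
        raise DegenerateSchemeError(
            f"{scheme.name}: singular system at m={m}"
        ) from err
    return float(sol[0])


def extrapolation_table(scheme, xs, ys, method="solve"):
    """One S_m per admissible start index; degenerate entries become NaN."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n = scheme.n_terms
    n_entries = len(ys) - (n - 1) - scheme.lookahead
    out = []
    for m in range(max(n_entries, 0)):
        try:
            out.append(e_algorithm(scheme, xs, ys, m, method))
        except DegenerateSchemeError:
            out.append(np.nan)
    return np.asarray(out)
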