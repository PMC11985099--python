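"""Error-bound families b(x).

An error bound encodes the convergence rate of a numerical method: the
simulator output f(x) at discretization parameters x in (0, inf)^d satisfies
f(x) - f(0) = O(b(x)), with b(x) > 0 for x != 0 and b(0) = 0.  The bound is
multiplied into a base covariance to form the nonstationary prior covariance
k_b(x, x') = b(x) b(x') k_e(x, x') of the Gauss-Richardson model.

The families provided here are the ones that routinely appear in numerical
analysis: a single monomial x^r in d = 1, additive per-dimension powers
sum_i w_i x_i^{r_i}, product powers prod_i x_i^{r_i}, and a general positive
polynomial with vanishing constant term.  The additive and product families
are *monotonically parametrized*: raising any component of r makes b(hx)
vanish faster as h -> 0, which is what makes the convergence order
identifiable from data (see :mod:`grextrap.orders`).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ErrorBound",
    "MonomialBound",
    "AdditivePowersBound",
    "ProductPowersBound",
    "CustomPolynomialBound",
]


def _as_points(x, d):
    """Coerce ``x`` to an (n, d) array, validating dimensions and sign."""
    arr = np.asarray(x, dtype=float)
    scalar_input = False
    if arr.ndim == 0:
        if d != 1:
            raise ValueError(f"scalar input for a bound of dimension d={d}")
        arr = arr.reshape(1, 1)
        scalar_input = True
    elif arr.ndim == 1:
        if d == 1 and arr.shape[0] != 1:
            # a batch of 1-d points
            arr = arr.reshape(-1, 1)
        else:
            if arr.shape[0] != d:
                raise ValueError(
                    f"point has dimension {arr.shape[0]}, bound expects d={d}"
                )
            arr = arr.reshape(1, d)
            scalar_input = True
    elif arr.ndim == 2:
        if arr.shape[1] != d:
            raise ValueError(
                f"points have dimension {arr.shape[1]}, bound expects d={d}"
            )
    else:
        raise ValueError("points must be at most 2-dimensional arrays")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite component in input point")
    if np.any(arr < 0):
        raise ValueError("negative component in input point; domain is [0, inf)^d")
    return arr, scalar_input


class ErrorBound:
    """Base class for error-bound families.

    Subclasses implement :meth:`_eval` on an (n, d) array of points.  All
    bounds satisfy b(x) >= 0 with equality iff x = 0 (componentwise).
    """

    form: str = "custom"

    def __init__(self, orders, d):
        orders = np.atleast_1d(np.asarray(orders, dtype=float))
        if np.any(orders < 0):
            raise ValueError("convergence orders must be nonnegative")
        self.orders = orders
        self.d = int(d)

    def __call__(self, x):
        pts, scalar = _as_points(x, self.d)
        vals = self._eval(pts)
        return float(vals[0]) if scalar else vals

    def _eval(self, pts):  # pragma: no cover - abstract
        raise NotImplementedError

    def eval_one(self, x):
        """Scalar evaluation preserving the input arithmetic type.

        Accepts a sequence of length d (or a scalar when d = 1) of floats or
        ``mpmath.mpf`` values; used by the extended-precision backend.
        """
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}(orders={self.orders.tolist()}, d={self.d})"


class MonomialBound(ErrorBound):
    """b(x) = x^r in dimension one; the workhorse for single-parameter methods."""

    form = "monomial_1d"

    def __init__(self, r):
        super().__init__([r], d=1)
        self.r = float(r)

    def _eval(self, pts):
        return pts[:, 0] ** self.r

    def eval_one(self, x):
        if isinstance(x, (list, tuple, np.ndarray)):
            x = x[0]
        return x**self.r

    def __repr__(self):
        return f"MonomialBound(r={self.r})"


class AdditivePowersBound(ErrorBound):
    """b(x) = sum_i w_i x_i^{r_i} with positive weights w."""

    form = "additive_powers"

    def __init__(self, orders, weights=None):
        orders = np.atleast_1d(np.asarray(orders, dtype=float))
        super().__init__(orders, d=orders.shape[0])
        if weights is None:
            weights = np.ones(self.d)
        self.weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if self.weights.shape[0] != self.d:
            raise ValueError("weights length must match dimension")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def _eval(self, pts):
        return (self.weights * pts**self.orders).sum(axis=1)

    def eval_one(self, x):
        if np.ndim(x) == 0:
            x = [x]
        return sum(
            w * xi**r for w, xi, r in zip(self.weights, x, self.orders)
        )


class ProductPowersBound(ErrorBound):
    """b(x) = prod_i x_i^{r_i}; vanishes when *any* component vanishes."""

    form = "product_powers"

    def __init__(self, orders):
        orders = np.atleast_1d(np.asarray(orders, dtype=float))
        super().__init__(orders, d=orders.shape[0])

    def _eval(self, pts):
        return np.prod(pts**self.orders, axis=1)

    def eval_one(self, x):
        if np.ndim(x) == 0:
            x = [x]
        out = 1
        for xi, r in zip(x, self.orders):
            out = out * xi**r
        return out


class CustomPolynomialBound(ErrorBound):
    """b(x) = sum_k c_k prod_i x_i^{e_{ki}} with c_k > 0 and each term of
    positive total degree, so that b(0) = 0 and b > 0 away from the origin on
    the positive orthant."""

    form = "custom_polynomial"

    def __init__(self, terms, d):
        # terms: iterable of (coefficient, exponent-vector)
        coeffs = []
        expos = []
        for c, e in terms:
            e = np.atleast_1d(np.asarray(e, dtype=float))
            if e.shape[0] != d:
                raise ValueError("exponent vector length must equal d")
            if c <= 0:
                raise ValueError("polynomial coefficients must be positive")
            if e.sum() <= 0:
                raise ValueError("each term must have positive total degree")
            coeffs.append(float(c))
            expos.append(e)
        if not coeffs:
            raise ValueError("at least one term required")
        self.coeffs = np.asarray(coeffs)
        self.expos = np.asarray(expos)
        super().__init__(self.expos.max(axis=0), d=d)

    def _eval(self, pts):
        # (n, K) matrix of monomials
        mono = np.prod(pts[:, None, :] ** self.expos[None, :, :], axis=2)
        return mono @ self.coeffs

    def eval_one(self, x):
        if np.ndim(x) == 0:
            x = [x]
        total = 0
        for c, e in zip(self.coeffs, self.expos):
            term = c
            for xi, ei in zip(x, e):
                term = term * xi**ei
            total = total + term
        return total


_FORMS = {
    "monomial_1d": MonomialBound,
    "additive_powers": AdditivePowersBound,
    "product_powers": ProductPowersBound,
    "custom_polynomial": CustomPolynomialBound,
}


def make_bound(form, orders, weights=None, d=None, terms=None):
    """Construct an :class:`ErrorBound` from a config-style description."""
    if form == "monomial_1d":
        orders = np.atleast_1d(orders)
        return MonomialBound(orders[0])
    if form == "additive_powers":
        return AdditivePowersBound(orders, weights)
    if form == "product_powers":
        return ProductPowersBound(orders)
    if form == "custom_polynomial":
        return CustomPolynomialBound(terms, d)
    raise ValueError(f"unknown bound form {form!r}")
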