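"""Base covariance kernels and the bound-weighted prior covariance.

The base kernel k_e models the *normalized error* e(x) = (f(x) - f(0))/b(x),
which is assumed smooth.  The catalogue is the one used throughout the
benchmark problems:

* Matern with half-integer smoothness s in {0, 1, 2} (Matern-1/2, -3/2, -5/2);
  samples are s-times differentiable.
* Wendland compactly supported polynomials of matching smoothness in d = 1,
  with support radius equal to the length-scale.
* Gaussian (squared exponential), infinitely smooth, in the anisotropic form
  exp(-sum_i (x_i - x_i')^2 / l_i^2).
* Polynomial kernel (1 + <x, x'>/l^2)^degree, which reproduces the space of
  polynomials of the given degree and recovers classical Richardson
  extrapolation as a special case of the GP posterior mean.

Anisotropy enters by coordinate-wise rescaling x / l before evaluating an
isotropic radial form.  :class:`ProductKernel` builds tensor products of
one-dimensional kernels with per-dimension smoothness, as used by the
multi-fidelity workflow.

:class:`BoundKernel` combines a bound and a base kernel into

    k_b(x, x') = b(x) b(x') k_e(x, x'),

which is positive semi-definite everywhere and positive definite on distinct
points away from the origin (for the strictly positive-definite base
families), and satisfies k_b(0, x) = 0 — the property that pins the GP at the
continuum limit.
"""

from __future__ import annotations

import numpy as np

from .exceptions import GRExtrapError

__all__ = [
    "Kernel",
    "Matern",
    "Wendland",
    "Gaussian",
    "Polynomial",
    "ProductKernel",
    "BoundKernel",
    "make_kernel",
]

_SQRT3 = np.sqrt(3.0)
_SQRT5 = np.sqrt(5.0)


def _pairwise_scaled(X, Y, lengthscales):
    """Euclidean distances between rows of X and Y after rescaling by l."""
    Xs = X / lengthscales
    Ys = Y / lengthscales
    d2 = (
        (Xs**2).sum(axis=1)[:, None]
        + (Ys**2).sum(axis=1)[None, :]
        - 2.0 * Xs @ Ys.T
    )
    return np.sqrt(np.maximum(d2, 0.0))


class Kernel:
    """Base class: symmetric positive (semi-)definite covariance k_e."""

    family: str = "base"
    smoothness: float | None = None

    def __init__(self, lengthscales=1.0, d=None):
        ls = np.atleast_1d(np.asarray(lengthscales, dtype=float))
        if np.any(ls <= 0):
            raise ValueError("length-scales must be positive")
        if d is not None and ls.shape[0] == 1 and d > 1:
            ls = np.full(d, ls[0])
        self.lengthscales = ls
        self.d = ls.shape[0] if d is None else int(d)

    def _coerce(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1) if self.d == 1 else X.reshape(1, -1)
        if X.shape[1] != self.d and self.lengthscales.shape[0] == 1:
            # isotropic kernel used in higher dimension
            self.lengthscales = np.full(X.shape[1], self.lengthscales[0])
            self.d = X.shape[1]
        if X.shape[1] != self.d:
            raise ValueError(f"points have dimension {X.shape[1]}, expected {self.d}")
        return X

    def __call__(self, X, Y=None):
        X = self._coerce(X)
        Y = X if Y is None else self._coerce(Y)
        return self._cross(X, Y)

    def _cross(self, X, Y):  # pragma: no cover - abstract
        raise NotImplementedError

    def eval_one(self, x, y):
        """Scalar evaluation preserving input arithmetic (mpmath-aware)."""
        raise NotImplementedError

    def diag(self, X):
        X = self._coerce(X)
        return np.array([self._cross(X[i : i + 1], X[i : i + 1])[0, 0] for i in range(X.shape[0])])


def _radial_u(x, y, lengthscales):
    """Scaled distance for scalar (possibly mpmath) inputs."""
    import mpmath

    if np.ndim(x) == 0:
        x = [x]
    if np.ndim(y) == 0:
        y = [y]
    s = mpmath.mpf(0)
    for xi, yi, li in zip(x, y, lengthscales):
        diff = (mpmath.mpf(xi) if isinstance(xi, float) else xi) - yi
        s += (diff / mpmath.mpf(li)) ** 2
    return mpmath.sqrt(s)


class Matern(Kernel):
    """Matern kernel with half-integer smoothness s in {0, 1, 2}."""

    family = "matern"

    def __init__(self, smoothness=2, lengthscales=1.0, d=None):
        super().__init__(lengthscales, d)
        if smoothness not in (0, 1, 2):
            raise GRExtrapError(
                f"Matern smoothness s={smoothness} outside the catalogue {{0, 1, 2}}"
            )
        self.smoothness = int(smoothness)

    def _cross(self, X, Y):
        u = _pairwise_scaled(X, Y, self.lengthscales)
        if self.smoothness == 0:
            return np.exp(-u)
        if self.smoothness == 1:
            return (1.0 + _SQRT3 * u) * np.exp(-_SQRT3 * u)
        v = _SQRT5 * u
        return (1.0 + v + v**2 / 3.0) * np.exp(-v)

    def eval_one(self, x, y):
        import mpmath

        u = _radial_u(x, y, self.lengthscales)
        if self.smoothness == 0:
            return mpmath.exp(-u)
        if self.smoothness == 1:
            v = mpmath.sqrt(3) * u
            return (1 + v) * mpmath.exp(-v)
        v = mpmath.sqrt(5) * u
        return (1 + v + v**2 / 3) * mpmath.exp(-v)


class Wendland(Kernel):
    """Compactly supported Wendland kernels in d = 1, smoothness s in {0, 1, 2}.

    Standard (d=1, k=s) parametrization with support radius equal to the
    length-scale: phi_0(u) = (1-u)_+, phi_1(u) = (1-u)_+^3 (3u+1),
    phi_2(u) = (1-u)_+^5 (8u^2 + 5u + 1).
    """

    family = "wendland"

    def __init__(self, smoothness=2, lengthscales=1.0):
        super().__init__(lengthscales, d=1)
        if smoothness not in (0, 1, 2):
            raise GRExtrapError(
                f"Wendland smoothness s={smoothness} outside the catalogue {{0, 1, 2}}"
            )
        self.smoothness = int(smoothness)

    @staticmethod
    def _phi(u, s):
        w = np.maximum(1.0 - u, 0.0)
        if s == 0:
            return w
        if s == 1:
            return w**3 * (3.0 * u + 1.0)
        return w**5 * (8.0 * u**2 + 5.0 * u + 1.0)

    def _cross(self, X, Y):
        u = _pairwise_scaled(X, Y, self.lengthscales)
        return self._phi(u, self.smoothness)

    def eval_one(self, x, y):
        import mpmath

        u = _radial_u(x, y, self.lengthscales)
        w = 1 - u
        if w <= 0:
            return mpmath.mpf(0)
        if self.smoothness == 0:
            return w
        if self.smoothness == 1:
            return w**3 * (3 * u + 1)
        return w**5 * (8 * u**2 + 5 * u + 1)


class Gaussian(Kernel):
    """Squared-exponential kernel exp(-sum_i (x_i - x_i')^2 / l_i^2)."""

    family = "gaussian"
    smoothness = np.inf

    def _cross(self, X, Y):
        u = _pairwise_scaled(X, Y, self.lengthscales)
        return np.exp(-(u**2))

    def eval_one(self, x, y):
        import mpmath

        u = _radial_u(x, y, self.lengthscales)
        return mpmath.exp(-(u**2))


class Polynomial(Kernel):
    """Polynomial kernel (1 + <x, x'>/l^2)^degree.

    Degree 0 is the constant kernel.  With degree n-2 this kernel reproduces
    pi_{n-2}, the polynomial space underlying Richardson extrapolation.
    """

    family = "polynomial"

    def __init__(self, degree, lengthscales=1.0, d=None):
        super().__init__(lengthscales, d)
        if degree < 0 or int(degree) != degree:
            raise ValueError("polynomial degree must be a nonnegative integer")
        self.degree = int(degree)
        self.smoothness = np.inf

    def _cross(self, X, Y):
        l2 = float(self.lengthscales[0]) ** 2
        return (1.0 + (X @ Y.T) / l2) ** self.degree

    def eval_one(self, x, y):
        import mpmath

        if np.ndim(x) == 0:
            x = [x]
        if np.ndim(y) == 0:
            y = [y]
        l2 = mpmath.mpf(float(self.lengthscales[0])) ** 2
        ip = mpmath.mpf(0)
        for xi, yi in zip(x, y):
            ip += mpmath.mpf(xi) * yi if isinstance(xi, float) else xi * yi
        return (1 + ip / l2) ** self.degree


class ProductKernel(Kernel):
    """Tensor product of one-dimensional kernels, one factor per dimension.

    Used by the multi-fidelity workflow where each discretization axis gets
    its own estimated smoothness and length-scale.
    """

    family = "product"

    def __init__(self, factors):
        factors = list(factors)
        if not factors:
            raise ValueError("at least one factor required")
        for f in factors:
            if f.d != 1:
                raise ValueError("factors must be one-dimensional kernels")
        self.factors = factors
        ls = np.array([f.lengthscales[0] for f in factors])
        super().__init__(ls, d=len(factors))
        self.smoothness = min(f.smoothness for f in factors)

    def _coerce(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1) if X.shape[0] == self.d else X.reshape(-1, 1)
        if X.shape[1] != self.d:
            raise ValueError(f"points have dimension {X.shape[1]}, expected {self.d}")
        return X

    def _cross(self, X, Y):
        out = np.ones((X.shape[0], Y.shape[0]))
        for i, f in enumerate(self.factors):
            out *= f(X[:, i : i + 1], Y[:, i : i + 1])
        return out

    def eval_one(self, x, y):
        if np.ndim(x) == 0:
            x = [x]
        if np.ndim(y) == 0:
            y = [y]
        out = 1
        for f, xi, yi in zip(self.factors, x, y):
            out = out * f.eval_one(xi, yi)
        return out


class BoundKernel:
    """Prior covariance k_b(x, x') = b(x) b(x') k_e(x, x')."""

    def __init__(self, bound, base):
        self.bound = bound
        self.base = base

    def __call__(self, X, Y=None):
        bX = np.atleast_1d(self.bound(X))
        bY = bX if Y is None else np.atleast_1d(self.bound(Y))
        return bX[:, None] * bY[None, :] * self.base(X, Y)

    def eval_one(self, x, y):
        return self.bound.eval_one(x) * self.bound.eval_one(y) * self.base.eval_one(x, y)

    def gram(self, X):
        """Symmetric PSD Gram matrix on distinct points away from the origin."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite entries in design points")
        if np.any(np.all(X == 0.0, axis=1)):
            raise ValueError("design contains the origin; k_b is degenerate there")
        # duplicate check
        n = X.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if np.array_equal(X[i], X[j]):
                    raise ValueError(f"duplicate design points at rows {i} and {j}")
        K = self(X)
        return 0.5 * (K + K.T)

    def gram_diagnostics(self, X):
        """Gram matrix plus its minimum eigenvalue for conditioning checks."""
        K = self.gram(X)
        eigs = np.linalg.eigvalsh(K)
        return K, float(eigs.min())

    def __repr__(self):
        return f"BoundKernel({self.bound!r}, {self.base!r})"


def make_kernel(family, smoothness=2, lengthscales=1.0, degree=None, d=None):
    """Construct a base kernel from a config-style description."""
    if family == "matern":
        return Matern(smoothness, lengthscales, d)
    if family == "wendland":
        return Wendland(smoothness, lengthscales)
    if family == "gaussian":
        return Gaussian(lengthscales, d)
    if family == "polynomial":
        if degree is None:
            raise ValueError("polynomial kernel requires a degree")
        return Polynomial(degree, lengthscales, d)
    raise ValueError(f"unknown kernel family {family!r}")
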