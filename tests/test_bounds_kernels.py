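"""Error-bound families, base kernels, and the bound-weighted covariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grextrap import (
    AdditivePowersBound,
    BoundKernel,
    CustomPolynomialBound,
    Gaussian,
    GRExtrapError,
    Matern,
    MonomialBound,
    Polynomial,
    ProductKernel,
    ProductPowersBound,
    Wendland,
    make_bound,
    make_kernel,
)


class TestErrorBounds:
    @pytest.mark.parametrize(
        "bound, x, expected",
        [
            (MonomialBound(2), 0.5, 0.25),
            (MonomialBound(2), 0.0, 0.0),
            (AdditivePowersBound([1, 2]), [0.1, 0.1], 0.11),
            (AdditivePowersBound([1, 2]), [0.0, 0.0], 0.0),
            (ProductPowersBound([1, 2]), [0.5, 0.5], 0.125),
            (ProductPowersBound([1, 2]), [0.0, 0.3], 0.0),
            (CustomPolynomialBound([(2.0, [1]), (3.0, [3])], d=1), 0.5, 1.375),
        ],
    )
    def test_evaluation(self, bound, x, expected):
        assert bound(x) == pytest.approx(expected, abs=1e-15)

    def test_vanishes_only_at_origin(self):
        b = AdditivePowersBound([0.5, 1.5], weights=[2.0, 3.0])
        assert b([0.0, 0.0]) == 0.0
        assert b([1e-8, 0.0]) > 0.0

    def test_dimension_and_sign_errors(self):
        b = AdditivePowersBound([1, 2])
        with pytest.raises(ValueError):
            b([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            b([-0.1, 0.2])

    @given(h=st.floats(0.01, 10.0), x=st.floats(0.01, 10.0),
           r=st.floats(0.0, 4.0))
    @settings(deadline=None, max_examples=50)
    def test_monomial_scaling(self, h, x, r):
        b = MonomialBound(r)
        assert b(h * x) == pytest.approx(h**r * b(x), rel=1e-10)

    @pytest.mark.parametrize("family", [AdditivePowersBound, ProductPowersBound])
    def test_monotone_parametrization(self, family):
        # b_{r+1}(h x) / b_r(h x) -> 0 along h = 2^{-j}
        x = np.array([0.7, 1.3])
        r = np.array([1.0, 2.0])
        lo, hi = family(r), family(r + 1.0)
        ratios = [hi(2.0**-j * x) / lo(2.0**-j * x) for j in range(1, 21)]
        assert all(b < a for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] < 1e-5

    def test_make_bound_dispatch(self):
        assert isinstance(make_bound("monomial_1d", 2), MonomialBound)
        assert isinstance(make_bound("additive_powers", [1, 2]),
                          AdditivePowersBound)
        with pytest.raises(ValueError):
            make_bound("nope", 1)


class TestBaseKernels:
    def test_unit_diagonal_and_constants(self):
        assert Gaussian()([0.3], [0.3])[0, 0] == pytest.approx(1.0)
        assert Polynomial(0)([0.1], [5.0])[0, 0] == pytest.approx(1.0)

    def test_matern52_closed_form(self):
        # (1 + sqrt5 u + 5 u^2/3) exp(-sqrt5 u) at u = 1
        u = 1.0
        expected = (1 + np.sqrt(5) * u + 5 * u**2 / 3) * np.exp(-np.sqrt(5) * u)
        assert Matern(2)([0.0], [1.0])[0, 0] == pytest.approx(expected, rel=1e-14)

    def test_unsupported_smoothness(self):
        with pytest.raises(GRExtrapError):
            Matern(3)
        with pytest.raises(GRExtrapError):
            Wendland(5)

    @pytest.mark.parametrize(
        "kernel",
        [Matern(0), Matern(1), Matern(2), Wendland(0), Wendland(2),
         Gaussian(), Polynomial(3)],
    )
    def test_symmetry(self, kernel, rng):
        X = rng.uniform(0.05, 1.0, (6, 1))
        K = kernel(X)
        np.testing.assert_allclose(K, K.T, rtol=1e-14)
        assert np.all(np.diag(K) > 0)

    def test_anisotropic_lengthscales(self):
        k = Gaussian(lengthscales=[1.0, 2.0])
        val = k(np.array([[0.0, 0.0]]), np.array([[1.0, 2.0]]))[0, 0]
        assert val == pytest.approx(np.exp(-(1.0 + 1.0)))

    def test_product_kernel_factorizes(self):
        k = ProductKernel([Matern(2, 0.5), Gaussian(lengthscales=2.0)])
        x = np.array([[0.2, 0.4]])
        y = np.array([[0.6, 0.1]])
        expected = (Matern(2, 0.5)([0.2], [0.6])[0, 0]
                    * Gaussian(lengthscales=2.0)([0.4], [0.1])[0, 0])
        assert k(x, y)[0, 0] == pytest.approx(expected, rel=1e-14)

    def test_eval_one_matches_vectorized(self):
        for kern in [Matern(0), Matern(1), Matern(2), Wendland(1), Gaussian(),
                     Polynomial(2)]:
            a, b = 0.37, 0.81
            assert float(kern.eval_one(a, b)) == pytest.approx(
                kern([a], [b])[0, 0], rel=1e-12
            )

    def test_make_kernel_dispatch(self):
        assert isinstance(make_kernel("matern", 1), Matern)
        assert isinstance(make_kernel("polynomial", degree=2), Polynomial)
        with pytest.raises(ValueError):
            make_kernel("polynomial")


class TestBoundKernel:
    def test_single_point_gram(self):
        bk = BoundKernel(MonomialBound(1), Matern(0))
        x = np.array([[0.5]])
        beta = 0.5
        K = bk.gram(x)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(beta**2 * 1.0)

    def test_vanishes_against_origin(self):
        bk = BoundKernel(MonomialBound(2), Gaussian())
        row = bk(np.array([[0.0]]), np.array([[0.3], [0.9]]))
        np.testing.assert_allclose(row, 0.0, atol=1e-15)

    def test_gram_validation_errors(self):
        bk = BoundKernel(MonomialBound(1), Matern(0))
        with pytest.raises(ValueError):
            bk.gram(np.array([[0.2], [0.2]]))
        with pytest.raises(ValueError):
            bk.gram(np.array([[0.0], [0.2]]))

    def test_gram_positive_definite(self, rng):
        bk = BoundKernel(MonomialBound(1), Matern(0))
        X = np.sort(rng.uniform(0.1, 1.0, 4)).reshape(-1, 1)
        _, min_eig = bk.gram_diagnostics(X)
        assert min_eig > 0

    @pytest.mark.parametrize("kernel", [Matern(0), Matern(2), Gaussian(),
                                        Wendland(1), Polynomial(2)])
    def test_psd_property(self, kernel, rng):
        # 50 random point sets: minimum eigenvalue >= -1e-10 * trace / n
        bk = BoundKernel(MonomialBound(1.5), kernel)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            X = rng.uniform(0.05, 2.0, (n, 1))
            X += np.arange(n).reshape(-1, 1) * 1e-6  # enforce distinctness
            K, min_eig = bk.gram_diagnostics(X)
            assert min_eig >= -1e-10 * np.trace(K) / n
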