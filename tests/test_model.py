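"""Scalar GRE posterior: point estimate, scale, prediction, intervals."""

import numpy as np
import pytest

from oracles import finite_k0_posterior

from grextrap import (
    BoundKernel,
    ConditioningError,
    GaussRichardson,
    Gaussian,
    Kernel,
    Matern,
    MonomialBound,
    Polynomial,
    SimulationLog,
    fit,
    scale_estimator,
)
from grextrap.classical import e_algorithm, richardson


class IdentityKernel(Kernel):
    """Test fixture: k(x, x') = 1 if x == x' else 0 (valid on finite sets)."""

    family = "identity"
    smoothness = 0

    def _cross(self, X, Y):
        return (np.abs(X[:, None, :] - Y[None, :, :]).sum(axis=2) == 0).astype(float)

    def eval_one(self, x, y):
        return 1.0 if list(x) == list(y) else 0.0


class UnitBound(MonomialBound):
    """b = x^0 = 1 on positive points (never evaluated at 0 in these tests)."""

    def __init__(self):
        super().__init__(0.0)


class TestFitBasics:
    def test_single_point_degenerate(self, matern2_bk):
        log = SimulationLog(np.array([[0.4]]), np.array([7.5]))
        res = fit(log, matern2_bk)
        assert res.mean_at_zero == pytest.approx(7.5)
        assert res.sigma2 == 0.0
        assert res.var_at_zero == 0.0

    def test_constant_data(self, matern2_bk):
        X = np.linspace(0.2, 1.0, 5).reshape(-1, 1)
        log = SimulationLog(X, np.full(5, 3.25))
        res = fit(log, matern2_bk)
        assert res.mean_at_zero == pytest.approx(3.25, rel=1e-10)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-10)

    def test_two_point_richardson_identity(self, cd_testbed):
        # with b(x) = x and a constant base kernel the two-point estimate is
        # the classical first-order extrapolation 2 f(h) - f(2h)
        h = 0.15
        fh, f2h = cd_testbed.evaluator(h), cd_testbed.evaluator(2 * h)
        log = SimulationLog(np.array([[h], [2 * h]]), np.array([fh, f2h]))
        res = fit(log, BoundKernel(MonomialBound(1), Polynomial(0)))
        assert res.mean_at_zero == pytest.approx(2 * fh - f2h, rel=1e-8)

    def test_mean_interpolates(self, simple_log, matern2_bk):
        res = fit(simple_log, matern2_bk)
        for xi, yi in zip(simple_log.X, simple_log.y):
            mean, var = res.predict(xi)
            assert mean == pytest.approx(yi, rel=1e-7)
            assert var <= 1e-7 * max(1.0, res.sigma2)

    def test_weights_sum_to_one(self, simple_log, matern2_bk):
        # the point estimate is an affine combination of the data: adding a
        # constant to y shifts the estimate by exactly that constant
        res = fit(simple_log, matern2_bk)
        shifted = SimulationLog(simple_log.X, simple_log.y + 11.0)
        res2 = fit(shifted, matern2_bk)
        assert res2.mean_at_zero == pytest.approx(res.mean_at_zero + 11.0,
                                                  rel=1e-9)

    def test_affine_equivariance(self, simple_log, matern2_bk):
        res = fit(simple_log, matern2_bk)
        a, c = -2.5, 4.0
        res2 = fit(SimulationLog(simple_log.X, a * simple_log.y + c),
                   matern2_bk)
        assert res2.mean_at_zero == pytest.approx(a * res.mean_at_zero + c,
                                                  rel=1e-9)
        assert res2.sigma2 == pytest.approx(a**2 * res.sigma2, rel=1e-8)
        assert res2.var_at_zero == pytest.approx(a**2 * res.var_at_zero,
                                                 rel=1e-8)

    def test_conditioning_error_names_near_duplicates(self):
        # a matrix that stays indefinite under any jitter escalation
        from grextrap.linalg import JitteredCholesky

        X = np.array([[0.5], [0.5 + 1e-12], [0.9]])
        K = -np.eye(3)
        with pytest.raises(ConditioningError) as exc:
            JitteredCholesky(K, X=X)
        assert exc.value.offending_pair == (0, 1)


class TestScaleEstimator:
    def test_hand_case_identity_gram(self):
        # K_b = I_2, y = (0, 2): sigma^2 = (1/2)[4 - 4/2] = 1
        log = SimulationLog(np.array([[1.0], [2.0]]), np.array([0.0, 2.0]))
        bk = BoundKernel(UnitBound(), IdentityKernel())
        assert scale_estimator(log, bk) == pytest.approx(1.0, rel=1e-10)

    def test_matches_direct_formula(self, simple_log, matern2_bk, rng):
        # numpy-inverse oracle for the quadratic form
        log = SimulationLog(simple_log.X, rng.normal(0, 1, simple_log.n))
        K = matern2_bk.gram(log.X)
        Ki = np.linalg.inv(K)
        ones = np.ones(log.n)
        expected = (log.y @ Ki @ log.y
                    - (ones @ Ki @ log.y) ** 2 / (ones @ Ki @ ones)) / log.n
        assert scale_estimator(log, matern2_bk) == pytest.approx(
            expected, rel=1e-8
        )

    def test_nonnegative_zero_iff_constant(self, matern2_bk, rng):
        X = np.linspace(0.2, 1.0, 5).reshape(-1, 1)
        assert scale_estimator(SimulationLog(X, np.full(5, -2.0)),
                               matern2_bk) == pytest.approx(0.0, abs=1e-9)
        noisy = scale_estimator(SimulationLog(X, rng.normal(0, 1, 5)),
                                matern2_bk)
        assert noisy > 0.0


class TestPredict:
    def test_zero_matches_closed_form(self, simple_log, matern2_bk):
        res = fit(simple_log, matern2_bk)
        mean, var = res.predict(np.array([0.0]))
        assert mean == pytest.approx(res.mean_at_zero)
        assert var == pytest.approx(res.var_at_zero)

    @pytest.mark.parametrize("x", [0.0, 0.35, 0.55])
    def test_finite_k0_limit(self, cd_testbed, x):
        # the improper-limit posterior is the k0 -> infinity limit of the
        # proper conjugate GP; discrepancy decreases along k0 = 1e4, 1e6, 1e8
        X = np.array([0.3, 0.7])
        y = np.array([cd_testbed.evaluator(v) for v in X])
        bk = BoundKernel(MonomialBound(2), Matern(2))
        res = fit(SimulationLog(X.reshape(-1, 1), y), bk)
        mean, var = res.predict(np.array([x]))
        unit_var = var / res.sigma2
        dmeans, dvars = [], []
        for k0 in (1e4, 1e6, 1e8):
            mo, vo = finite_k0_posterior(X, y, bk, k0, np.array([x]))
            dmeans.append(abs(mo - mean) / max(1.0, abs(mean)))
            dvars.append(abs(vo - unit_var) / max(1e-12, abs(unit_var)))
        assert dmeans[-1] <= 1e-5 and dvars[-1] <= 1e-5
        floor = 1e-14
        assert all(b <= a or b < floor for a, b in zip(dmeans, dmeans[1:]))

    def test_richardson_equivalence(self, rng):
        # polynomial base kernel of degree n-2 with b in pi_1 reproduces the
        # E-algorithm output of classical Richardson extrapolation
        for n in (2, 3, 4):
            for _ in range(3):
                xs = np.sort(rng.uniform(0.3, 1.5, n))[::-1]
                ys = rng.normal(0, 1, n)
                log = SimulationLog(xs.reshape(-1, 1), ys)
                bk = BoundKernel(MonomialBound(1), Polynomial(n - 2))
                m0 = fit(log, bk).mean_at_zero
                sm = e_algorithm(richardson(n), xs, ys, 0)
                assert m0 == pytest.approx(sm, rel=1e-5, abs=1e-5)


class TestCredibleInterval:
    def test_degenerate_when_scale_zero(self, matern2_bk):
        log = SimulationLog(np.array([[0.4]]), np.array([2.0]))
        ci = fit(log, matern2_bk).credible_interval(0.05)
        assert ci.lower == ci.upper == 2.0

    def test_standard_normal_quantile(self, simple_log, matern2_bk):
        res = fit(simple_log, matern2_bk)
        res.var_at_zero = 1.0
        res.mean_at_zero = 0.0
        ci = res.credible_interval(0.05)
        assert ci.lower == pytest.approx(-1.959964, abs=1e-6)
        assert ci.upper == pytest.approx(1.959964, abs=1e-6)

    def test_nested_in_alpha(self, simple_log, matern2_bk):
        res = fit(simple_log, matern2_bk)
        wide = res.credible_interval(0.01)
        narrow = res.credible_interval(0.10)
        assert wide.lower <= narrow.lower <= narrow.upper <= wide.upper

    def test_alpha_validation(self, simple_log, matern2_bk):
        res = fit(simple_log, matern2_bk)
        with pytest.raises(ValueError):
            res.credible_interval(0.0)
        with pytest.raises(ValueError):
            res.credible_interval(1.5)


class TestResultsInterface:
    def test_summary_and_json(self, simple_log, matern2_bk):
        res = GaussRichardson(simple_log, matern2_bk).fit()
        text = res.summary()
        assert "Estimate of f(0)" in text
        import json

        payload = json.loads(res.to_json())
        assert payload["n"] == 5
        assert payload["interval"][0] <= payload["mean_at_zero"]

    def test_plot_smoke(self, simple_log, matern2_bk):
        matplotlib = pytest.importorskip("matplotlib")
        matplotlib.use("Agg")
        res = fit(simple_log, matern2_bk)
        ax = res.plot()
        assert ax.get_xlabel() == "discretization parameter x"

    def test_from_dataframe_roundtrip(self, simple_log, matern2_bk):
        df = simple_log.to_dataframe()
        model = GaussRichardson.from_dataframe(df, matern2_bk.bound,
                                               matern2_bk.base)
        res = model.fit()
        ref = fit(simple_log, matern2_bk)
        assert res.mean_at_zero == pytest.approx(ref.mean_at_zero)
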