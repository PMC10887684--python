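import math

import numpy as np
import pytest

import wextropy as wx
from wextropy.exceptions import DomainError

SQRT_PI = math.sqrt(math.pi)


class TestTrueValues:
    @pytest.mark.parametrize(
        "make, extropy, weighted",
        [
            (lambda: wx.uniform01(), -0.5, -0.25),
            (lambda: wx.exponential(1.0), -0.25, -0.125),
            (lambda: wx.exponential(2.0), -0.5, -0.125),
            (lambda: wx.power2x(), -2.0 / 3.0, -0.5),
            (lambda: wx.rayleigh1(), -SQRT_PI / 8.0, -0.25),
            (lambda: wx.lognormal(0, 1), None, -1.0 / (4.0 * SQRT_PI)),
        ],
    )
    def test_closed_forms_agree_with_quadrature(self, make, extropy, weighted):
        dist = make()
        assert wx.true_weighted_extropy(dist) == pytest.approx(weighted, rel=1e-10)
        assert wx.true_weighted_extropy(dist, method="quadrature") == pytest.approx(
            weighted, abs=1e-8
        )
        if extropy is not None:
            assert wx.true_extropy(dist) == pytest.approx(extropy, rel=1e-10)
        assert wx.true_extropy(dist, method="quadrature") == pytest.approx(
            wx.true_extropy(dist), abs=1e-8
        )

    @pytest.mark.parametrize("rate", [0.25, 1.0, 4.0])
    def test_exponential_weighted_extropy_is_rate_free(self, rate):
        dist = wx.exponential(rate)
        assert wx.true_weighted_extropy(dist, method="quadrature") == pytest.approx(
            -0.125, abs=1e-8
        )

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 1.066, 2.0])
    def test_lognormal_closed_form_in_sigma(self, sigma):
        dist = wx.lognormal(0.7, sigma)
        assert wx.true_weighted_extropy(dist, method="quadrature") == pytest.approx(
            -1.0 / (4.0 * sigma * SQRT_PI), abs=1e-8
        )


def _brute_force_we(fhat, lo, hi, m=2_000_001):
    """Dense-trapezoid oracle for -1/2 \\int x fhat(x)^2 dx."""
    x = np.linspace(lo, hi, m)
    f = fhat(x)
    return -0.5 * float(np.trapezoid(x * f * f, x))


class TestEstimatorOracles:
    """Each estimator must equal an independent brute-force evaluation of
    its defining integral/sum on a fixed n=50 sample."""

    def test_lkde_estimator(self, exp_sample50):
        h = 0.4
        data = exp_sample50.values
        root = math.sqrt(2 * math.pi)

        def fhat(x):
            # direct formula, written independently of the package path
            out = np.zeros_like(x)
            pos = x > 0
            for xi in data:
                u = (np.log(x[pos]) - math.log(xi)) / h
                out[pos] += np.exp(-0.5 * u * u) / root
            return out / (len(data) * h * np.where(pos, x, 1.0))

        oracle = _brute_force_we(fhat, 1e-9, data.max() * math.exp(8 * h))
        assert wx.we_lkde(exp_sample50, h=h).value == pytest.approx(oracle, abs=1e-6)

    def test_kde_estimator(self):
        sample = wx.LifetimeSample([1.0, 2.0, 3.0])
        h = 0.5
        root = math.sqrt(2 * math.pi)

        def fhat(x):
            out = np.zeros_like(x)
            for xi in [1.0, 2.0, 3.0]:
                u = (x - xi) / h
                out += np.exp(-0.5 * u * u) / root
            return out / (3 * h)

        oracle = _brute_force_we(fhat, 0.0, 3.0 + 8 * h)
        assert wx.we_kde(sample, h=h).value == pytest.approx(oracle, abs=1e-6)

    def test_empirical_estimator(self, exp_sample50):
        h = 0.3
        xs = np.sort(exp_sample50.values)
        root = math.sqrt(2 * math.pi)
        total = 0.0
        for i in range(len(xs) - 1):
            f = np.mean(np.exp(-0.5 * ((xs[i] - xs) / h) ** 2)) / (root * h)
            total += (xs[i + 1] ** 2 - xs[i] ** 2) * f * f
        oracle = -0.25 * total
        assert wx.we_empirical(exp_sample50, h=h).value == pytest.approx(oracle, abs=1e-9)


class TestLkdeEstimator:
    def test_direct_and_fubini_forms_agree(self, exp_sample50):
        """The weighted integral and its Fubini double-integral rewriting
        are the same functional of the fitted density."""
        direct = wx.we_lkde(exp_sample50, h=0.4, form="direct").value
        double = wx.we_lkde(exp_sample50, h=0.4, form="fubini").value
        assert double == pytest.approx(direct, abs=1e-6)

    def test_rejects_nonpositive_data(self):
        with pytest.raises(DomainError):
            wx.we_lkde([1.0, 0.0, 2.0])

    def test_default_bandwidth_is_log_scale_plugin(self, exp_sample50):
        est = wx.we_lkde(exp_sample50)
        assert est.h == pytest.approx(
            wx.plugin_bandwidth(exp_sample50, scale="log").h
        )


class TestKdeAndEmpiricalEstimators:
    def test_order_invariance(self, exp_sample50):
        perm = np.random.default_rng(5).permutation(exp_sample50.values)
        assert wx.we_kde(perm, h=0.3).value == pytest.approx(
            wx.we_kde(exp_sample50, h=0.3).value, abs=1e-12
        )
        assert wx.we_empirical(perm, h=0.3).value == pytest.approx(
            wx.we_empirical(exp_sample50, h=0.3).value, abs=1e-12
        )

    def test_empirical_single_spacing_arithmetic(self):
        # one spacing: -1/4 (2^2 - 1^2) fhat(1)^2
        sample = wx.LifetimeSample([1.0, 2.0])
        h = 1.0
        c = float(wx.kde_fit(sample, h).evaluate(1.0)[0])
        assert wx.we_empirical(sample, h=h).value == pytest.approx(-0.75 * c * c)

    def test_empirical_tied_sample_is_zero(self):
        assert wx.we_empirical([2.0, 2.0, 2.0], h=0.5).value == 0.0

    def test_minimum_sample_size(self):
        with pytest.raises(DomainError):
            wx.we_empirical([1.5], h=0.5)


class TestSignProperty:
    def test_all_estimators_nonpositive_on_positive_samples(self, all_distributions):
        rng = np.random.default_rng(99)
        for dist in all_distributions:
            sample = wx.LifetimeSample(dist.sampler(40, rng))
            assert wx.we_lkde(sample).value <= 0
            assert wx.we_kde(sample).value <= 0
            assert wx.we_empirical(sample).value <= 0


class TestParametric:
    def test_exponential_value_is_rate_free(self, exp_sample50):
        est = wx.we_parametric(exp_sample50, "exponential")
        assert est.value == -0.125
        assert est.family == "exponential"

    def test_lognormal_at_injected_parameters(self, exp_sample50):
        est = wx.we_parametric(exp_sample50, "lognormal",
                               params={"sigma": 1.066, "mu": 1.756})
        assert est.value == pytest.approx(-0.1323, abs=1e-4)

    def test_lognormal_ml_fit_matches_log_moments(self):
        rng = np.random.default_rng(11)
        data = np.exp(0.3 + 0.8 * rng.standard_normal(500))
        est = wx.we_parametric(data, "lognormal")
        sigma_hat = np.log(data).std(ddof=0)
        assert est.value == pytest.approx(-1 / (4 * sigma_hat * SQRT_PI), rel=1e-12)

    def test_nonpositive_data_rejected(self):
        with pytest.raises(DomainError):
            wx.we_parametric([1.0, 0.0], "lognormal")

    def test_unsupported_family(self, exp_sample50):
        with pytest.raises(DomainError):
            wx.we_parametric(exp_sample50, "weibull")


class TestTheoryFunctionals:
    def test_bias_scales_as_h_squared(self, exp1):
        b1 = wx.we_lkde_bias_theory(exp1, 0.1)
        b2 = wx.we_lkde_bias_theory(exp1, 0.2)
        assert b2 / b1 == pytest.approx(4.0, abs=1e-9)

    def test_variance_scales_as_one_over_nh(self, exp1):
        v = wx.we_lkde_var_theory(exp1, 100, 0.2)
        assert wx.we_lkde_var_theory(exp1, 200, 0.2) == pytest.approx(v / 2, rel=1e-12)
        assert wx.we_lkde_var_theory(exp1, 100, 0.4) == pytest.approx(v / 2, rel=1e-9)

    def test_exponential_against_dense_grid_fubini_oracle(self, exp1):
        """Brute-force evaluation of the wedge integrals on a dense grid."""
        x = np.linspace(1e-7, 25.0, 200_001)
        f = exp1.pdf(x)
        inner_bias = (f + 3 * x * exp1.pdf_d1(x) + x * x * exp1.pdf_d2(x)) * f
        inner_var = f**3 / x
        # \int_0^U dy \int_y^U g = \int_0^U x g(x) dx on the grid
        oracle_bias = -0.5 * 0.1**2 * np.trapezoid(x * inner_bias, x)
        oracle_var = wx.GAUSSIAN.roughness / (100 * 0.1) * np.trapezoid(x * inner_var, x)
        assert wx.we_lkde_bias_theory(exp1, 0.1) == pytest.approx(oracle_bias, rel=1e-4)
        assert wx.we_lkde_var_theory(exp1, 100, 0.1) == pytest.approx(oracle_var, rel=1e-4)

    def test_amise_minimiser(self, exp1):
        fun = wx.we_lkde_amise(exp1, 100, 0.5)
        h_opt = fun.h_opt
        amise = lambda h: wx.we_lkde_amise(exp1, 100, h).amise
        a0 = amise(h_opt)
        # stationary point: symmetric difference derivative ~ 0
        eps = 1e-4 * h_opt
        deriv = (amise(h_opt + eps) - amise(h_opt - eps)) / (2 * eps)
        assert abs(deriv) < 1e-6 * a0 / h_opt + 1e-12
        assert a0 <= amise(0.5 * h_opt)
        assert a0 <= amise(2.0 * h_opt)

    def test_amise_h_opt_n_rate(self, exp1):
        f1 = wx.we_lkde_amise(exp1, 50, 0.3)
        f2 = wx.we_lkde_amise(exp1, 50 * 32, 0.3)
        assert f2.h_opt / f1.h_opt == pytest.approx(0.5, abs=1e-9)
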