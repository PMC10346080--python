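"""Core AFT model: likelihood, fitting, and the Weibull special case."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import flexaft as fa
from flexaft.aft_core import _Engine, _resolve_knots
from flexaft.splines import KnotVector


class TestAccelerationFactor:
    def test_baseline_subject(self):
        assert fa.acceleration_factor(np.zeros(3), np.array([1.0, -2, 0.3])) == 1.0

    @pytest.mark.parametrize("b,expected", [(0.5, np.exp(-0.5)), (-0.5, np.exp(0.5))])
    def test_direct_exponentiation(self, b, expected):
        assert np.isclose(fa.acceleration_factor([1.0], [b]), expected)


class TestModelFunctions:
    kv = KnotVector(np.array([-2.0, 0.5, 2.0]))
    gamma3 = np.array([0.2, 1.1, 0.05])

    def test_df1_is_weibull_log_cumhaz(self):
        kv = KnotVector(np.array([-3.0, 3.0]))
        loglam, zeta, beta = -1.5, 1.3, 0.5
        t, x = 2.0, np.array([1.0])
        got = fa.log_cumhaz(t, x, [loglam, zeta], [beta], kv)
        assert np.isclose(got, loglam + zeta * np.log(t * np.exp(-beta)))

    def test_gamma0_at_unit_time_baseline(self):
        kv = KnotVector(np.array([0.0, 1.0, 2.0]))
        got = fa.log_cumhaz(1.0, np.zeros(1), [0.7, 1.0, 0.2], np.zeros(1), kv)
        assert np.isclose(got, 0.7)

    def test_df1_hazard_is_weibull(self):
        kv = KnotVector(np.array([-3.0, 3.0]))
        lam, zeta, beta = 0.3, 1.4, 0.4
        t, x = 1.7, np.array([1.0])
        got = fa.hazard(t, x, [np.log(lam), zeta], [beta], kv)
        expected = lam * zeta * t ** (zeta - 1) * np.exp(-beta * zeta)
        assert np.isclose(got, expected, rtol=1e-10)

    def test_hazard_matches_cumhaz_finite_difference(self):
        t = 1.2
        h = 1e-6
        x, beta = np.array([0.5]), np.array([-0.3])
        H = lambda tt: np.exp(fa.log_cumhaz(tt, x, self.gamma3, beta, self.kv))
        fd = (H(t + h) - H(t - h)) / (2 * h)
        got = fa.hazard(t, x, self.gamma3, beta, self.kv)
        assert np.isclose(got, fd, rtol=1e-5)

    def test_aft_time_rescaling_identity(self):
        # S(t|X) = S0(t * phi) exactly for the constant-AF model
        beta = np.array([0.6])
        x = np.array([1.0])
        phi = fa.acceleration_factor(x, beta)
        for t in (0.3, 1.0, 2.5):
            lhs = fa.survival(t, x, self.gamma3, beta, self.kv)
            rhs = fa.survival(t * phi, np.zeros(1), self.gamma3, np.zeros(1), self.kv)
            assert np.isclose(lhs, rhs, rtol=1e-12)

    def test_hazard_time_rescaling(self):
        # h(t|phi) = phi * h0(phi * t)
        beta = np.array([-np.log(2.0)])  # phi = 2
        x = np.array([1.0])
        for t in (0.4, 1.1):
            lhs = fa.hazard(t, x, self.gamma3, beta, self.kv)
            rhs = 2.0 * fa.hazard(2.0 * t, np.zeros(1), self.gamma3, np.zeros(1), self.kv)
            assert np.isclose(lhs, rhs, rtol=1e-10)

    def test_survival_equals_exp_neg_cumhaz(self):
        t = np.array([0.5, 1.5, 3.0])
        s = fa.survival(t, np.zeros(1), self.gamma3, np.zeros(1), self.kv)
        H = np.exp(fa.log_cumhaz(t, np.zeros(1), self.gamma3, np.zeros(1), self.kv))
        assert np.allclose(s, np.exp(-H))


class TestLoglik:
    def test_censored_exponential_closed_form(self):
        # single censored subject, df=1: ll = -lambda * y^zeta * e^{-X beta zeta}
        lam, zeta, beta, y, xv = 0.25, 1.2, 0.4, 3.0, 1.0
        data = fa.SurvivalData(t=[y], delta=[0.0], X=pd.DataFrame({"x": [xv]}))
        spec = fa.ModelSpec(df=1, covariates=["x"])
        kv = KnotVector(np.array([-5.0, 5.0]))
        ll = fa.loglik([np.log(lam), zeta, beta], data, spec, knots=kv)
        assert np.isclose(ll, -lam * y**zeta * np.exp(-xv * beta * zeta))

    def test_entry_equal_exit_contributes_nothing(self):
        y = np.array([2.0, 3.0])
        data = fa.SurvivalData(t=y, delta=[0.0, 0.0],
                               X=pd.DataFrame({"x": [0.0, 1.0]}),
                               t0=y * (1 - 1e-12))
        spec = fa.ModelSpec(df=1, covariates=["x"])
        kv = KnotVector(np.array([-5.0, 5.0]))
        ll = fa.loglik([0.1, 1.1, 0.3], data, spec, knots=kv)
        assert abs(ll) < 1e-9

    def test_negative_slope_at_event_gives_sentinel(self):
        data = fa.SurvivalData(t=[1.0], delta=[1.0], X=pd.DataFrame({"x": [0.0]}))
        spec = fa.ModelSpec(df=1, covariates=["x"])
        kv = KnotVector(np.array([-5.0, 5.0]))
        ll = fa.loglik([0.0, -1.0, 0.0], data, spec, knots=kv)
        assert ll <= -1e11

    def test_matches_hazard_survival_quadrature(self):
        """ll_i = delta*log h(y) + log S(y) - log S(t0), with S from
        numerical quadrature of the hazard (independent of the closed form)."""
        rng = np.random.default_rng(5)
        kv = KnotVector(np.array([-1.5, 0.0, 1.5]))
        gamma = np.array([-0.3, 1.2, 0.08])
        beta = np.array([0.4])
        y = rng.uniform(0.3, 4.0, 10)
        t0 = np.where(rng.uniform(size=10) < 0.5, rng.uniform(0.01, 0.2, 10), 0.0)
        delta = (rng.uniform(size=10) < 0.6).astype(float)
        xv = rng.integers(0, 2, 10).astype(float)
        data = fa.SurvivalData(t=y, delta=delta, X=pd.DataFrame({"x": xv}), t0=t0)
        spec = fa.ModelSpec(df=2, covariates=["x"])
        ll = fa.loglik(np.concatenate([gamma, beta]), data, spec, knots=kv)

        def logS(t, x):
            if t == 0:
                return 0.0
            val, _ = quad(lambda s: fa.hazard(s, np.array([x]), gamma, beta, kv,
                                              warn=False), 0, t, limit=400)
            return -val

        expected = sum(
            d * np.log(fa.hazard(yy, np.array([xx]), gamma, beta, kv, warn=False))
            + logS(yy, xx) - logS(tt0, xx)
            for yy, d, xx, tt0 in zip(y, delta, xv, t0)
        )
        assert np.isclose(ll, expected, rtol=1e-7, atol=1e-6)


def test_score_matches_finite_differences(weibull_data):
    """Analytic gradient vs central finite differences at random points."""
    spec = fa.ModelSpec(df=3, covariates=["x"])
    knots, tk = _resolve_knots(weibull_data, spec)
    eng = _Engine(weibull_data, spec, knots, tk)
    rng = np.random.default_rng(17)
    base = np.array([-1.6, 1.3, 0.0, 0.0, 0.5])
    for _ in range(10):
        theta = base + 0.1 * rng.standard_normal(base.size)
        if eng.loglik(theta) <= -1e11:
            continue
        ga = eng.score(theta)
        gn = np.empty_like(ga)
        for j in range(theta.size):
            h = 1e-6 * max(1, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            gn[j] = (eng.loglik(tp) - eng.loglik(tm)) / (2 * h)
        assert np.allclose(ga, gn, rtol=1e-5, atol=1e-4)


class TestFit:
    def test_df1_equals_weibull_aft(self, weibull_data, weibull_fit_df1):
        from flexaft.comparators import fit_weibull_aft

        wb = fit_weibull_aft(weibull_data)
        assert abs(weibull_fit_df1.loglik - wb.loglik) < 1e-4
        assert abs(weibull_fit_df1.beta[0] - wb.coef["x"]) < 1e-4

    def test_weibull_parameter_recovery(self, weibull_fit_df1):
        # truth: lambda=0.2, zeta=1.3, beta=0.5
        f = weibull_fit_df1
        i = f.param_names.index("x")
        se = np.sqrt(f.vcov[i, i])
        assert abs(f.beta[0] - 0.5) < 3 * se
        assert abs(f.gamma[1] - 1.3) < 0.1

    def test_spline_fit_nests_weibull(self, weibull_fit_df1, weibull_fit_df3):
        assert weibull_fit_df3.loglik >= weibull_fit_df1.loglik - 1e-6

    def test_refit_is_bit_reproducible(self, weibull_data):
        spec = fa.ModelSpec(df=2, covariates=["x"])
        f1 = fa.fit(weibull_data, spec)
        f2 = fa.fit(weibull_data, spec)
        assert np.array_equal(f1.theta, f2.theta)
        assert f1.loglik == f2.loglik

    def test_aft_structural_identity_of_fit(self, weibull_fit_df3):
        f = weibull_fit_df3
        phi = fa.acceleration_factor([1.0], f.beta)
        t = np.array([0.5, 1.0, 2.0, 4.0])
        s1 = fa.survival(t, np.array([1.0]), f.gamma, f.beta, f.knots)
        s0 = fa.survival(t * phi, np.zeros(1), f.gamma, np.zeros(1), f.knots)
        assert np.allclose(s1, s0, rtol=1e-12)

    def test_no_events_rejected(self):
        data = fa.SurvivalData(t=[1.0, 2.0], delta=[0.0, 0.0],
                               X=pd.DataFrame({"x": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="events"):
            fa.fit(data, fa.ModelSpec(df=1, covariates=["x"]))

    def test_intercept_column_rejected(self):
        with pytest.raises(ValueError, match="intercept"):
            fa.SurvivalData(t=[1.0, 2.0], delta=[1.0, 1.0],
                            X=pd.DataFrame({"c": [1.0, 1.0]}))


class TestInformationCriteria:
    def test_arithmetic(self):
        aic, bic = fa.information_criteria(-100.0, 3, 50)
        assert aic == 206.0
        assert np.isclose(bic, 200 + 3 * np.log(50))

    def test_zero_parameters(self):
        aic, bic = fa.information_criteria(-80.0, 0, 100)
        assert aic == bic == 160.0

    def test_fitted_object_criteria_consistent(self, weibull_fit_df3):
        f = weibull_fit_df3
        p = f.n_params
        assert np.isclose(f.aic, -2 * f.loglik + 2 * p)
        assert np.isclose(f.bic, -2 * f.loglik + p * np.log(f.n_events))


def test_wald_coverage_correctly_specified():
    """95% Wald CIs for beta cover the truth at close to nominal rate."""
    covered = 0
    nrep = 60
    for s in range(nrep):
        scn = fa.MixtureWeibullScenario(p=1.0, lambda1=0.2, gamma1=1.3,
                                        beta=0.5, n=600, seed=20_000 + s,
                                        admin_censor=8.0)
        d = fa.simulate_mixture_weibull_aft(scn)
        f = fa.fit(d, fa.ModelSpec(df=1, covariates=["x"]))
        i = f.param_names.index("x")
        se = np.sqrt(f.vcov[i, i])
        covered += abs(f.beta[0] - 0.5) <= 1.96 * se
    # binomial(60, .95): central 99.9% region is roughly [51, 60]
    assert covered >= 51
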