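"""Parametric AFT comparators and PH plumbing fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

import flexaft as fa
from flexaft import comparators as cmp
from flexaft.comparators import _genf_logf_logS, _gengamma_logf_logS


@pytest.fixture(scope="module")
def exp_data():
    """Exponential AFT data (zeta=1), n=3000."""
    scn = fa.MixtureWeibullScenario(p=1.0, lambda1=0.3, gamma1=1.0, beta=0.4,
                                    n=3000, seed=77, admin_censor=10.0)
    return fa.simulate_mixture_weibull_aft(scn)


class TestWeibull:
    def test_exponential_shape_recovered(self, exp_data):
        f = cmp.fit_weibull_aft(exp_data)
        assert f.converged
        zeta = np.exp(f.coef["log_zeta"])
        se_log = f.se("log_zeta")
        assert abs(f.coef["log_zeta"]) < 3 * se_log
        assert 0.9 < zeta < 1.1

    def test_null_covariate(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(2.0, 1500)
        x = rng.integers(0, 2, 1500).astype(float)
        d = fa.SurvivalData(t=t, delta=np.ones(1500), X=pd.DataFrame({"x": x}))
        f = cmp.fit_weibull_aft(d)
        assert abs(f.coef["x"]) < 3 * f.se("x")

    def test_agrees_with_lifelines(self, weibull_data):
        from lifelines import WeibullAFTFitter

        df = weibull_data.X.copy()
        df["t"] = weibull_data.t
        df["d"] = weibull_data.delta
        ll_fit = WeibullAFTFitter().fit(df, duration_col="t", event_col="d")
        ours = cmp.fit_weibull_aft(weibull_data)
        # lifelines scales time by exp(x beta): same log-AF convention
        assert abs(ours.loglik - ll_fit.log_likelihood_) < 1e-3
        assert abs(ours.coef["x"] - ll_fit.params_[("lambda_", "x")]) < 1e-4


class TestGenGamma:
    def test_weibull_submodel_recovered(self, weibull_data):
        f = cmp.fit_gengamma_aft(weibull_data)
        assert f.converged
        assert abs(f.coef["Q"] - 1.0) < 3 * f.se("Q")

    def test_nests_weibull_loglik(self, weibull_data):
        wb = cmp.fit_weibull_aft(weibull_data)
        gg = cmp.fit_gengamma_aft(weibull_data)
        assert gg.loglik >= wb.loglik - 1e-4

    def test_density_integrates_to_survival(self):
        # S(t) from the closed form equals the integral of the density
        mu, sigma, Q = 0.5, 0.8, 0.6
        for t in (0.5, 2.0):
            w = (np.log(t) - mu) / sigma
            _, logS = _gengamma_logf_logS(np.array([w]), sigma, Q)

            def dens(tt):
                ww = (np.log(tt) - mu) / sigma
                lf, _ = _gengamma_logf_logS(np.array([ww]), sigma, Q)
                return np.exp(lf[0]) / tt

            integral, _ = quad(dens, t, np.inf, limit=400)
            assert np.isclose(np.exp(logS[0]), integral, rtol=1e-6)


class TestGenF:
    def test_density_integrates_to_survival(self):
        mu, sigma, Q, P = 0.3, 0.7, 0.4, 0.6
        for t in (0.5, 1.5, 4.0):
            w = (np.log(t) - mu) / sigma
            _, logS = _genf_logf_logS(np.array([w]), sigma, Q, P)

            def dens(tt):
                ww = (np.log(tt) - mu) / sigma
                lf, _ = _genf_logf_logS(np.array([ww]), sigma, Q, P)
                return np.exp(lf[0]) / tt

            integral, _ = quad(dens, t, np.inf, limit=400)
            assert np.isclose(np.exp(logS[0]), integral, rtol=1e-6)

    def test_nests_gengamma(self, bimodal_data):
        gg = cmp.fit_gengamma_aft(bimodal_data)
        gf = cmp.fit_genf_aft(bimodal_data)
        if gg.converged and gf.converged:
            assert gf.loglik >= gg.loglik - 1e-4

    def test_pathological_fixture_reports_not_raises(self):
        # 6 subjects, heavy ties: 4-parameter family cannot be pinned down
        d = fa.SurvivalData(t=[1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                            delta=[1, 1, 0, 1, 0, 0],
                            X=pd.DataFrame({"x": [0, 1, 0, 1, 0, 1.0]}))
        f = cmp.fit_genf_aft(d)
        assert isinstance(f.converged, bool)


class TestExponentialPH:
    def test_single_group_closed_form_rate(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        delta = np.array([1.0, 0.0, 1.0, 1.0])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        # two groups: rate_g = events_g / persontime_g
        d = fa.SurvivalData(t=t, delta=delta, X=pd.DataFrame({"x": x}))
        f = cmp.fit_exponential_ph(d)
        rate0 = 1.0 / 3.0   # 1 event / 3 person-years in x=0
        rate1 = 2.0 / 7.0   # 2 events / 7 person-years in x=1
        assert np.isclose(f.coef["const"], np.log(rate0), atol=1e-6)
        assert np.isclose(f.coef["x"], np.log(rate1 / rate0), atol=1e-6)

    def test_ph_sign_opposite_of_aft_on_exponential_data(self, exp_data):
        ph = cmp.fit_exponential_ph(exp_data)
        aft = cmp.fit_weibull_aft(exp_data)
        # exponential AFT log AF beta corresponds to PH coefficient -beta
        assert np.isclose(ph.coef["x"], -aft.coef["x"], atol=0.05)


class TestCox:
    def test_matches_hand_coded_partial_likelihood(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        delta = np.array([1, 1, 0, 1, 1, 0.0])
        x = np.array([1, 0, 1, 1, 0, 0.0])
        d = fa.SurvivalData(t=t, delta=delta, X=pd.DataFrame({"x": x}))
        f = cmp.fit_cox_ph(d)

        def neg_pl(b):
            pl = 0.0
            for i in range(6):
                if delta[i]:
                    risk = t >= t[i]
                    pl += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return -pl

        res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert np.isclose(f.coef["x"], res.x, atol=1e-5)

    def test_null_covariate(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(1.0, 800)
        x = rng.integers(0, 2, 800).astype(float)
        d = fa.SurvivalData(t=t, delta=np.ones(800), X=pd.DataFrame({"x": x}))
        f = cmp.fit_cox_ph(d)
        assert abs(f.coef["x"]) < 3 * f.se("x")

    def test_agrees_with_exponential_ph_on_exponential_data(self, exp_data):
        ph = cmp.fit_exponential_ph(exp_data)
        cox = cmp.fit_cox_ph(exp_data)
        assert abs(cox.coef["x"] - ph.coef["x"]) < 3 * ph.se("x")


def test_nesting_chain(weibull_data):
    """ll_weibull <= ll_gengamma <= ll_genF, and flexaft(df=1) == weibull."""
    wb = cmp.fit_weibull_aft(weibull_data)
    gg = cmp.fit_gengamma_aft(weibull_data)
    gf = cmp.fit_genf_aft(weibull_data)
    assert wb.loglik <= gg.loglik + 1e-4
    if gf.converged:
        assert gg.loglik <= gf.loglik + 1e-4
    f1 = fa.fit(weibull_data, fa.ModelSpec(df=1, covariates=["x"]))
    assert abs(f1.loglik - wb.loglik) < 1e-4
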