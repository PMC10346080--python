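import numpy as np
import pytest

import flexaft as fa


@pytest.fixture(scope="session")
def weibull_data():
    """n=2000 draws from a true Weibull AFT (lambda=0.2, zeta=1.3, beta=0.5)."""
    scn = fa.MixtureWeibullScenario(p=1.0, lambda1=0.2, gamma1=1.3, beta=0.5,
                                    n=2000, seed=42, admin_censor=8.0)
    return fa.simulate_mixture_weibull_aft(scn)


@pytest.fixture(scope="session")
def weibull_fit_df1(weibull_data):
    return fa.fit(weibull_data, fa.ModelSpec(df=1, covariates=["x"]))


@pytest.fixture(scope="session")
def weibull_fit_df3(weibull_data):
    return fa.fit(weibull_data, fa.ModelSpec(df=3, covariates=["x"]))


@pytest.fixture(scope="session")
def bimodal_data():
    """Mixture baseline with a hump-then-rise hazard; beta=0.5, n=1500."""
    scn = fa.MIXTURE_PRESETS["bimodal"]
    import dataclasses
    return fa.simulate_mixture_weibull_aft(
        dataclasses.replace(scn, beta=0.5, n=1500, seed=7))
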