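"""Post-fit predictions with delta-method uncertainty.

Survival is monitored on the log(-log S) scale — the scale on which the
model is linear in its spline coefficients — with the standard error from
first-order variance propagation: se = sqrt(g' V g) where g is the gradient
of the transform with respect to all free parameters and V the fitted
covariance.  Confidence limits are built on the transformed scale and
back-transformed, so they respect the [0, 1] range of S and positivity of
acceleration factors by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aft_core import FittedAFT
from .splines import rcs_basis, rcs_deriv
from .tvc import eta_td, phi_td

Z95 = 1.959963984540054

__all__ = ["PredictionTable", "predict_survival", "predict_af", "summarize_af", "Z95"]


@dataclass
class PredictionTable:
    times: np.ndarray
    estimate: np.ndarray
    se: np.ndarray          # on the transformed scale
    ci_low: np.ndarray      # back-transformed
    ci_high: np.ndarray
    scale_label: str

    def __post_init__(self) -> None:
        n = self.times.size
        for arr in (self.estimate, self.se, self.ci_low, self.ci_high):
            if arr.size != n:
                raise ValueError("prediction columns must have equal length")
        if np.any(self.ci_low > self.estimate) or np.any(self.estimate > self.ci_high):
            raise ValueError("confidence limits cross the point estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "estimate": self.estimate, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def _transform_gradients(fitted: FittedAFT, X_row, times):
    """Value and parameter-gradient of s(log(t * phi(X, t))) per time point."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    X_row = np.atleast_1d(np.asarray(X_row, dtype=float))
    effects = fitted.effects()
    x_vals = fitted.tvc_values(X_row) if effects else np.empty(0)
    log_t = np.log(times)
    phi = np.atleast_1d(phi_td(X_row, times, fitted.beta, effects, x_vals))
    u = log_t + np.log(phi)
    B = np.atleast_2d(rcs_basis(u, fitted.knots))
    sp = np.atleast_2d(rcs_deriv(u, fitted.knots)) @ fitted.gamma[1:]
    value = fitted.gamma[0] + B @ fitted.gamma[1:]
    m = times.size
    G = np.zeros((m, fitted.n_params))
    G[:, 0] = 1.0
    G[:, 1: fitted.knots.df + 1] = B
    off = fitted.knots.df + 1
    for k in range(fitted.beta.size):
        G[:, off + k] = -sp * X_row[k]
    off += fitted.beta.size
    for x_p, eff in zip(x_vals, effects):
        Bt = np.atleast_2d(rcs_basis(log_t, eff.knots_t))
        G[:, off: off + eff.knots_t.df] = -(sp * x_p)[:, None] * Bt
        off += eff.knots_t.df
    return value, G


def predict_survival(fitted: FittedAFT, X_row, times, level: float = 0.95) -> PredictionTable:
    """S(t|X) with a delta-method CI built on the log(-log S) scale."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    value, G = _transform_gradients(fitted, X_row, times)
    var = np.einsum("ij,jk,ik->i", G, fitted.vcov, G)
    se = np.sqrt(np.maximum(var, 0.0))
    est = np.exp(-np.exp(value))
    # log(-log S) is decreasing in S: upper transform limit -> lower S limit
    lo = np.exp(-np.exp(value + z * se))
    hi = np.exp(-np.exp(value - z * se))
    return PredictionTable(times, est, se, lo, hi, "loglogS")


def predict_af(fitted: FittedAFT, X_row, times, level: float = 0.95) -> PredictionTable:
    """Instantaneous acceleration factor eta(t|X) with a log-scale delta CI.

    With no time-dependent terms eta is the constant exp(-X beta).
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    X_row = np.atleast_1d(np.asarray(X_row, dtype=float))
    effects = fitted.effects()
    x_vals = fitted.tvc_values(X_row) if effects else np.empty(0)
    log_t = np.log(times)
    eta = np.atleast_1d(eta_td(X_row, times, fitted.beta, effects, x_vals, warn=False))
    if np.any(eta <= 0):
        raise ValueError("eta(t) <= 0: log-scale interval undefined at some times")
    m = times.size
    G = np.zeros((m, fitted.n_params))
    off = fitted.knots.df + 1
    for k in range(fitted.beta.size):
        G[:, off + k] = -X_row[k]
    off += fitted.beta.size
    if effects:
        w = np.ones(m)
        for x_p, eff in zip(x_vals, effects):
            w -= x_p * eff.s_prime(log_t)
        for x_p, eff in zip(x_vals, effects):
            Bt = np.atleast_2d(rcs_basis(log_t, eff.knots_t))
            Btp = np.atleast_2d(rcs_deriv(log_t, eff.knots_t))
            G[:, off: off + eff.knots_t.df] = (
                -x_p * Bt - (x_p / w)[:, None] * Btp
            )
            off += eff.knots_t.df
    var = np.einsum("ij,jk,ik->i", G, fitted.vcov, G)
    se = np.sqrt(np.maximum(var, 0.0))
    log_eta = np.log(eta)
    lo = np.exp(log_eta - z * se)
    hi = np.exp(log_eta + z * se)
    return PredictionTable(times, eta, se, lo, hi, "logAF")


def summarize_af(fitted: FittedAFT, covariate: str, level: float = 0.95) -> dict:
    """Constant log-AF and AF summaries for one covariate.

    The regression coefficient beta is the log acceleration factor:
    exp(beta) multiplies survival time (a value below 1 shortens it), while
    phi = exp(-X beta) is the equivalent rescaling of time inside the
    baseline survival function.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    idx = fitted.param_names.index(covariate)
    est = float(fitted.theta[idx])
    se = float(np.sqrt(fitted.vcov[idx, idx]))
    return {
        "covariate": covariate,
        "log_af": {"estimate": est, "se": se,
                   "ci_low": est - z * se, "ci_high": est + z * se},
        "af": {"estimate": float(np.exp(est)),
               "ci_low": float(np.exp(est - z * se)),
               "ci_high": float(np.exp(est + z * se))},
    }
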