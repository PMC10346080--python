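"""Time-dependent acceleration factors.

A constant acceleration factor multiplies time itself: S(t|X) = S0(t * phi).
To let the effect of a covariate vary over follow-up, the model works on the
cumulative scale, replacing ``t * phi`` with ``t * phi(X, t)`` where

    phi(X, t) = exp(-X beta - sum_p x_p s(log t | gamma_p, k_p)),

each ``s(log t | gamma_p, k_p)`` being a restricted cubic spline of log time
for the p-th time-dependent effect.  The instantaneous (interpretable)
acceleration factor is recovered from the cumulative one through

    eta(X, t) = d/dt [ t * phi(X, t) ] = phi(X, t) * (1 - sum_p x_p s'(log t)),

so no integration is ever needed.  The tvc spline carries no intercept
column: the time-constant part of the effect is identified by beta_p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .splines import KnotVector, rcs_basis, rcs_deriv

__all__ = [
    "TimeDependentEffect",
    "phi_td",
    "eta_td",
    "hazard_td",
    "survival_td",
    "log_cumhaz_td",
]


@dataclass(frozen=True)
class TimeDependentEffect:
    """Spline-in-log-time effect of one covariate on the cumulative time scale."""

    covariate: str
    knots_t: KnotVector
    gamma_t: np.ndarray

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gamma_t, dtype=float))
        if g.size != self.knots_t.df:
            raise ValueError(
                f"gamma_t for {self.covariate!r} has length {g.size}, "
                f"expected df_t={self.knots_t.df}"
            )
        object.__setattr__(self, "gamma_t", g)

    def s(self, log_t) -> np.ndarray:
        """Spline value s(log t | gamma_p, k_p) (no intercept)."""
        return np.atleast_2d(rcs_basis(np.atleast_1d(log_t), self.knots_t)) @ self.gamma_t

    def s_prime(self, log_t) -> np.ndarray:
        return np.atleast_2d(rcs_deriv(np.atleast_1d(log_t), self.knots_t)) @ self.gamma_t


def _tvc_sum(x_vals, times, effects):
    """sum_p x_p s_p(log t) and sum_p x_p s_p'(log t), vectorised in t."""
    log_t = np.log(np.atleast_1d(np.asarray(times, dtype=float)))
    s_sum = np.zeros_like(log_t)
    sp_sum = np.zeros_like(log_t)
    for x_p, eff in zip(x_vals, effects):
        if x_p == 0.0:
            continue
        s_sum += x_p * eff.s(log_t)
        sp_sum += x_p * eff.s_prime(log_t)
    return s_sum, sp_sum


def phi_td(X_row, times, beta, effects, tvc_values=None):
    """Cumulative-scale acceleration factor phi(X, t).

    ``tvc_values`` are the covariate values entering the time-dependent
    terms; by default they are looked up by position in ``X_row`` via each
    effect's index being supplied separately by the caller, so here the
    caller passes the values explicitly (the fitted-model wrappers do this).
    With no effects this is the constant exp(-X beta).
    """
    X_row = np.atleast_1d(np.asarray(X_row, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    lin = float(X_row @ beta)
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if not effects:
        out = np.full(t.shape, np.exp(-lin))
    else:
        x_vals = _effect_values(X_row, effects, tvc_values)
        s_sum, _ = _tvc_sum(x_vals, t, effects)
        out = np.exp(-lin - s_sum)
    return out[0] if np.ndim(times) == 0 else out


def _effect_values(X_row, effects, tvc_values):
    if tvc_values is not None:
        return np.atleast_1d(np.asarray(tvc_values, dtype=float))
    # default: effects refer to leading columns of X_row by covariate order
    if len(effects) > X_row.size:
        raise ValueError("more time-dependent effects than covariate values")
    return X_row[: len(effects)]


def eta_td(X_row, times, beta, effects, tvc_values=None, warn=True):
    """Instantaneous acceleration factor eta(X, t) = d/dt [t phi(X, t)]."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    phi = np.atleast_1d(phi_td(X_row, t, beta, effects, tvc_values))
    if effects:
        x_vals = _effect_values(np.atleast_1d(np.asarray(X_row, float)), effects, tvc_values)
        _, sp_sum = _tvc_sum(x_vals, t, effects)
        eta = phi * (1.0 - sp_sum)
    else:
        eta = phi.copy()
    if warn and np.any(eta <= 0):
        warnings.warn("eta(t) <= 0 at some times (time-reversal region)", stacklevel=2)
    return eta[0] if np.ndim(times) == 0 else eta


def log_cumhaz_td(times, X_row, gamma, knots0, beta, effects, tvc_values=None):
    """log H(t|X) = s(log(t * phi(X, t)) | gamma, k0)."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    phi = np.atleast_1d(phi_td(X_row, t, beta, effects, tvc_values))
    u = np.log(t) + np.log(phi)
    gamma = np.asarray(gamma, dtype=float)
    s = gamma[0] + np.atleast_2d(rcs_basis(u, knots0)) @ gamma[1:]
    return s[0] if np.ndim(times) == 0 else s


def hazard_td(times, X_row, gamma, knots0, beta, effects, tvc_values=None, warn=True):
    """h(t|X) = exp(s(u)) * s'(u) / t * (1 - sum_p x_p s_p'(log t)), u = log(t phi(X,t)).

    The chain-rule factor s' is evaluated at the full argument
    log(t * phi(X, t)).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    phi = np.atleast_1d(phi_td(X_row, t, beta, effects, tvc_values))
    u = np.log(t) + np.log(phi)
    gamma = np.asarray(gamma, dtype=float)
    s = gamma[0] + np.atleast_2d(rcs_basis(u, knots0)) @ gamma[1:]
    sp = np.atleast_2d(rcs_deriv(u, knots0)) @ gamma[1:]
    if effects:
        x_vals = _effect_values(np.atleast_1d(np.asarray(X_row, float)), effects, tvc_values)
        _, sp_sum = _tvc_sum(x_vals, t, effects)
        w = 1.0 - sp_sum
    else:
        w = np.ones_like(t)
    h = np.exp(s) * sp * w / t
    if warn and np.any(h < 0):
        warnings.warn("negative fitted hazard (non-monotone cumulative hazard)", stacklevel=2)
    return h[0] if np.ndim(times) == 0 else h


def survival_td(times, X_row, gamma, knots0, beta, effects, tvc_values=None):
    """S(t|X) = exp(-exp(s(log(t phi(X, t)))))."""
    s = log_cumhaz_td(times, X_row, gamma, knots0, beta, effects, tvc_values)
    return np.exp(-np.exp(s))
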