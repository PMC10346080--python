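"""Flexible parametric accelerated failure time model.

The model places a restricted cubic spline on the log cumulative hazard of
accelerated time:

    log H(t | X) = s(log(t * phi(X)) | gamma, k0),   phi(X) = exp(-X beta).

With ``df = 1`` the spline is linear and the model is exactly a Weibull AFT
(``log H = gamma_0 + gamma_1 log(t phi)``); higher ``df`` adds restricted
cubic terms at interior knots, giving the baseline essentially arbitrary
smooth shape while keeping the interpretation of ``exp(-beta)`` as an
acceleration factor.  Estimation is full maximum likelihood with delayed
entry (left truncation), using Newton iterations with step halving and an
analytic score; the covariance is the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .splines import KnotVector, place_knots, rcs_basis, rcs_deriv, rcs_deriv2
from .tvc import TimeDependentEffect

__all__ = [
    "SurvivalData",
    "TvcTerm",
    "ModelSpec",
    "FittedAFT",
    "acceleration_factor",
    "log_cumhaz",
    "hazard",
    "survival",
    "loglik",
    "score",
    "fit",
    "information_criteria",
]

_SENTINEL = -1e12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SurvivalData:
    """Subject-level survival data: entry/exit times, events, covariates.

    ``X`` carries no intercept column; the spline intercept gamma_0 plays
    that role and a constant column would be unidentifiable.
    """

    t: np.ndarray
    delta: np.ndarray
    X: pd.DataFrame
    t0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.t0 is None:
            self.t0 = np.zeros_like(self.t)
        self.t0 = np.asarray(self.t0, dtype=float)
        if not isinstance(self.X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame")
        n = self.t.size
        if self.delta.size != n or self.t0.size != n or len(self.X) != n:
            raise ValueError("t, t0, delta and X must have the same length")
        if np.any(~np.isfinite(self.t)) or np.any(self.t <= 0):
            raise ValueError("exit times must be positive and finite")
        if np.any(self.t0 < 0) or np.any(self.t0 >= self.t):
            raise ValueError("entry times must satisfy 0 <= t0 < t")
        if not np.all(np.isin(self.delta, (0.0, 1.0))):
            raise ValueError("event indicator must be 0/1")
        if self.X.isna().any().any():
            raise ValueError("covariates contain missing values")
        if len(set(self.X.columns)) != len(self.X.columns):
            raise ValueError("covariate column names must be unique")
        for c in self.X.columns:
            col = np.asarray(self.X[c], dtype=float)
            if n > 1 and np.allclose(col, col[0]) and np.allclose(col[0], 1.0):
                raise ValueError(
                    f"column {c!r} is a constant intercept; gamma_0 already "
                    "plays that role (drop the column)"
                )

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())


@dataclass(frozen=True)
class TvcTerm:
    """Request for a time-dependent effect of one covariate with df_t spline columns."""

    covariate: str
    df_t: int = 1


@dataclass
class ModelSpec:
    """Baseline df, covariates and optional time-dependent effect terms."""

    df: int = 3
    covariates: Sequence[str] = ()
    tvc: Sequence[TvcTerm] = ()
    knots: KnotVector | None = None
    tvc_knots: dict | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("baseline df must be >= 1")
        names = set(self.covariates)
        for term in self.tvc:
            if term.covariate not in names:
                raise ValueError(
                    f"tvc covariate {term.covariate!r} is not in covariates"
                )


@dataclass
class FittedAFT:
    gamma: np.ndarray
    beta: np.ndarray
    tvc_gamma: dict
    vcov: np.ndarray
    loglik: float
    aic: float
    bic: float
    converged: bool
    n_events: int
    n: int
    knots: KnotVector
    tvc_knots: dict
    spec: ModelSpec
    param_names: list
    n_iter: int = 0
    neg_sprime_fraction: float = 0.0

    @property
    def theta(self) -> np.ndarray:
        parts = [self.gamma, self.beta]
        parts += [self.tvc_gamma[t.covariate] for t in self.spec.tvc]
        return np.concatenate(parts)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def effects(self) -> list:
        """TimeDependentEffect objects at the fitted coefficients."""
        return [
            TimeDependentEffect(t.covariate, self.tvc_knots[t.covariate],
                                self.tvc_gamma[t.covariate])
            for t in self.spec.tvc
        ]

    def tvc_values(self, X_row) -> np.ndarray:
        idx = [list(self.spec.covariates).index(t.covariate) for t in self.spec.tvc]
        X_row = np.atleast_1d(np.asarray(X_row, dtype=float))
        return X_row[idx]

    def summary_dict(self) -> dict:
        z = 1.959963984540054
        se = np.sqrt(np.diag(self.vcov))
        out = {
            "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
            "converged": self.converged, "n": self.n, "n_events": self.n_events,
            "knots": self.knots.knots.tolist(),
            "coefficients": {},
        }
        for name, est, s in zip(self.param_names, self.theta, se):
            entry = {"estimate": float(est), "se": float(s),
                     "ci_low": float(est - z * s), "ci_high": float(est + z * s)}
            if name in self.spec.covariates:
                # beta is the log acceleration factor: exp(beta) multiplies
                # survival time (phi = exp(-X beta) rescales time inside S0)
                entry["af"] = float(np.exp(est))
                entry["af_ci_low"] = float(np.exp(est - z * s))
                entry["af_ci_high"] = float(np.exp(est + z * s))
            out["coefficients"][name] = entry
        return out


# ---------------------------------------------------------------------------
# model functions (constant acceleration factor)
# ---------------------------------------------------------------------------

def acceleration_factor(X_row, beta) -> float:
    """phi = exp(-X beta): the factor multiplying time."""
    X_row = np.atleast_1d(np.asarray(X_row, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return float(np.exp(-X_row @ beta))


def _s_eval(u, gamma, knots: KnotVector):
    gamma = np.asarray(gamma, dtype=float)
    return gamma[0] + np.atleast_2d(rcs_basis(np.atleast_1d(u), knots)) @ gamma[1:]


def _s_prime(u, gamma, knots: KnotVector):
    gamma = np.asarray(gamma, dtype=float)
    return np.atleast_2d(rcs_deriv(np.atleast_1d(u), knots)) @ gamma[1:]


def log_cumhaz(time, X_row, gamma, beta, knots: KnotVector):
    """log H(t|X) = s(log(t phi(X))) for the constant-AF model."""
    t = np.atleast_1d(np.asarray(time, dtype=float))
    u = np.log(t) - float(np.atleast_1d(X_row) @ np.atleast_1d(beta))
    out = _s_eval(u, gamma, knots)
    return out[0] if np.ndim(time) == 0 else out


def hazard(time, X_row, gamma, beta, knots: KnotVector, warn=True):
    """h(t|X) = exp(s(u)) * s'(u) / t with u = log(t phi)."""
    t = np.atleast_1d(np.asarray(time, dtype=float))
    u = np.log(t) - float(np.atleast_1d(X_row) @ np.atleast_1d(beta))
    s = _s_eval(u, gamma, knots)
    sp = _s_prime(u, gamma, knots)
    if warn and np.any(sp < 0):
        warnings.warn("s'(u) < 0: fitted cumulative hazard is locally decreasing",
                      stacklevel=2)
    out = np.exp(s) * sp / t
    return out[0] if np.ndim(time) == 0 else out


def survival(time, X_row, gamma, beta, knots: KnotVector):
    """S(t|X) = exp(-exp(s(log(t phi))))."""
    out = np.exp(-np.exp(log_cumhaz(np.atleast_1d(time), X_row, gamma, beta, knots)))
    return out[0] if np.ndim(time) == 0 else out


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------

class _Engine:
    """Precomputes data-side quantities for fast loglik/score evaluation.

    Parameter vector layout: [gamma_0..gamma_df, beta_1..beta_c,
    gamma_p (df_t values) per time-dependent effect, in spec order].
    """

    def __init__(self, data: SurvivalData, spec: ModelSpec,
                 knots: KnotVector, tvc_knots: dict):
        self.data = data
        self.spec = spec
        self.knots = knots
        self.tvc_knots = tvc_knots
        self.a = np.log(data.t)
        self.has_entry = data.t0 > 0
        self.a0 = np.where(self.has_entry, np.log(np.where(self.has_entry, data.t0, 1.0)), 0.0)
        self.X = np.asarray(data.X[list(spec.covariates)], dtype=float) \
            if spec.covariates else np.zeros((data.n, 0))
        self.delta = data.delta
        self.events = data.delta == 1.0
        # tvc: covariate values and precomputed bases at log t and log t0
        self.tvc_x = []
        self.tvc_B = []      # basis at exit log-time, (n, df_t)
        self.tvc_Bp = []     # first derivative at exit log-time
        self.tvc_B0 = []     # basis at entry log-time
        for term in spec.tvc:
            kv = tvc_knots[term.covariate]
            self.tvc_x.append(np.asarray(data.X[term.covariate], dtype=float))
            self.tvc_B.append(np.atleast_2d(rcs_basis(self.a, kv)))
            self.tvc_Bp.append(np.atleast_2d(rcs_deriv(self.a, kv)))
            self.tvc_B0.append(np.atleast_2d(rcs_basis(self.a0, kv)))
        self.n_gamma = knots.df + 1
        self.n_beta = self.X.shape[1]
        self.tvc_sizes = [tvc_knots[t.covariate].df for t in spec.tvc]
        self.n_params = self.n_gamma + self.n_beta + sum(self.tvc_sizes)
        self.T = np.eye(self.n_gamma)

    def set_transform(self, T: np.ndarray | None) -> None:
        """Linear reparameterisation of the baseline spline coefficients.

        The raw truncated-power basis is badly conditioned at moderate df
        (cubic terms of log time are nearly collinear); the optimizer works
        with gamma-tilde where gamma_raw = T gamma-tilde and the augmented
        basis is right-multiplied by T.  Identity by default, so the public
        loglik/score contract stays on the raw scale.
        """
        self.T = np.eye(self.n_gamma) if T is None else np.asarray(T, float)

    def _aug(self, u, order: int = 0):
        """Augmented (intercept-first) basis of the requested derivative order."""
        fn = (rcs_basis, rcs_deriv, rcs_deriv2)[order]
        n = u.size
        out = np.empty((n, self.n_gamma))
        out[:, 0] = 1.0 if order == 0 else 0.0
        out[:, 1:] = np.atleast_2d(fn(u, self.knots))
        return out @ self.T

    def unpack(self, theta):
        g = theta[: self.n_gamma]
        b = theta[self.n_gamma: self.n_gamma + self.n_beta]
        gp, off = [], self.n_gamma + self.n_beta
        for sz in self.tvc_sizes:
            gp.append(theta[off: off + sz])
            off += sz
        return g, b, gp

    def param_names(self):
        names = [f"gamma{j}" for j in range(self.n_gamma)]
        names += list(self.spec.covariates)
        for term, sz in zip(self.spec.tvc, self.tvc_sizes):
            names += [f"{term.covariate}:t{j + 1}" for j in range(sz)]
        return names

    def _linpred(self, b, gp):
        """e = -X beta - sum_p x_p s_p(log t), and the entry-time analogue."""
        e = -(self.X @ b) if self.n_beta else np.zeros(self.data.n)
        e0 = e.copy()
        w = np.ones(self.data.n)
        for x_p, B, Bp, B0, g_p in zip(self.tvc_x, self.tvc_B, self.tvc_Bp,
                                       self.tvc_B0, (gp or [])):
            e -= x_p * (B @ g_p)
            e0 -= x_p * (B0 @ g_p)
            w -= x_p * (Bp @ g_p)
        return e, e0, w

    def loglik(self, theta):
        g, b, gp = self.unpack(theta)
        e, e0, w = self._linpred(b, gp)
        u = self.a + e
        s = self._aug(u, 0) @ g
        sp = self._aug(u, 1) @ g
        ev = self.events
        if np.any(sp[ev] <= 0) or np.any(w[ev] <= 0):
            return _SENTINEL
        with np.errstate(over="ignore"):
            H = np.exp(s)
        ll = np.where(ev, s - self.a + np.log(np.where(ev, sp, 1.0))
                      + np.log(np.where(ev, w, 1.0)), 0.0) - H
        if np.any(self.has_entry):
            u0 = self.a0 + e0
            s0 = self._aug(u0, 0) @ g
            with np.errstate(over="ignore"):
                H0 = np.exp(s0)
            ll = ll + np.where(self.has_entry, H0, 0.0)
        total = float(np.sum(ll))
        if not np.isfinite(total):
            return _SENTINEL
        return total

    def score(self, theta):
        """Analytic gradient of the log likelihood."""
        g, b, gp = self.unpack(theta)
        e, e0, w = self._linpred(b, gp)
        u = self.a + e
        B = self._aug(u, 0)
        Bp = self._aug(u, 1)
        Bpp = self._aug(u, 2)
        s = B @ g
        sp = Bp @ g
        spp = Bpp @ g
        d = self.delta
        with np.errstate(over="ignore"):
            H = np.exp(s)
        safe_sp = np.where(sp != 0, sp, 1.0)
        grad_gamma = (d[:, None] * (B + Bp / safe_sp[:, None])
                      - H[:, None] * B)
        # d ll / du at exit times
        dl_du = d * (sp + spp / safe_sp) - H * sp
        if np.any(self.has_entry):
            u0 = self.a0 + e0
            B0 = self._aug(u0, 0)
            sp0 = self._aug(u0, 1) @ g
            s0 = B0 @ g
            with np.errstate(over="ignore"):
                H0 = np.exp(s0)
            H0 = np.where(self.has_entry, H0, 0.0)
            grad_gamma = grad_gamma + H0[:, None] * B0
            dl_du0 = H0 * sp0
        else:
            dl_du0 = np.zeros_like(dl_du)
        grad = [*np.sum(grad_gamma, axis=0)]
        # beta: du/dbeta_k = -x_k at both exit and entry
        if self.n_beta:
            gbeta = -(self.X.T @ (dl_du + dl_du0))
            grad.extend(gbeta)
        # tvc gammas
        safe_w = np.where(w != 0, w, 1.0)
        for x_p, Bt, Btp, Bt0 in zip(self.tvc_x, self.tvc_B, self.tvc_Bp,
                                     self.tvc_B0):
            contrib = -(x_p * dl_du)[:, None] * Bt \
                      - (x_p * dl_du0)[:, None] * Bt0 \
                      - (d * x_p / safe_w)[:, None] * Btp
            grad.extend(np.sum(contrib, axis=0))
        return np.asarray(grad)

    def fd_hessian(self, theta, h_scale=1e-5):
        """Observed Hessian by central differences of the analytic score."""
        p = theta.size
        H = np.empty((p, p))
        for j in range(p):
            h = h_scale * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            H[:, j] = (self.score(tp) - self.score(tm)) / (2 * h)
        return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# public likelihood wrappers
# ---------------------------------------------------------------------------

def _resolve_knots(data: SurvivalData, spec: ModelSpec, phi_hat=None):
    """Knot placement: baseline knots on uncensored log accelerated time.

    The acceleration factor is unknown before fitting, so ``phi_hat`` from a
    Weibull (df=1) pilot fit is used; with ``phi_hat=None`` the raw log event
    times are used (always the case for the pilot itself, whose basis does
    not depend on interior knots).  tvc knots use unaccelerated log event
    times since those splines are functions of log t.
    """
    ev = data.delta == 1.0
    if not np.any(ev):
        raise ValueError("no events in the data")
    log_t_ev = np.log(data.t[ev])
    if spec.knots is not None:
        knots = spec.knots
    else:
        u_ev = log_t_ev + (np.log(phi_hat[ev]) if phi_hat is not None else 0.0)
        if spec.df == 1 and np.ptp(u_ev) == 0:
            u_ev = np.concatenate([u_ev, u_ev + 1.0])  # degenerate; basis unused
        knots = place_knots(u_ev, spec.df)
    tvc_knots = dict(spec.tvc_knots or {})
    for term in spec.tvc:
        if term.covariate not in tvc_knots:
            tvc_knots[term.covariate] = place_knots(log_t_ev, term.df_t)
    return knots, tvc_knots


def loglik(theta, data: SurvivalData, spec: ModelSpec,
           knots: KnotVector | None = None, tvc_knots: dict | None = None):
    """Delayed-entry log likelihood at parameter vector ``theta``.

    Knots must be fixed before evaluation; if not given they are placed on
    the raw uncensored log event times.
    """
    if knots is None or (spec.tvc and tvc_knots is None):
        k, tk = _resolve_knots(data, spec)
        knots = knots or k
        tvc_knots = tvc_knots or tk
    eng = _Engine(data, spec, knots, tvc_knots or {})
    return eng.loglik(np.asarray(theta, dtype=float))


def score(theta, data: SurvivalData, spec: ModelSpec,
          knots: KnotVector | None = None, tvc_knots: dict | None = None):
    """Analytic gradient of :func:`loglik` with respect to ``theta``."""
    if knots is None or (spec.tvc and tvc_knots is None):
        k, tk = _resolve_knots(data, spec)
        knots = knots or k
        tvc_knots = tvc_knots or tk
    eng = _Engine(data, spec, knots, tvc_knots or {})
    return eng.score(np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _newton(eng: _Engine, theta0, gtol=1e-8, max_iter=200):
    """Newton ascent with step halving; quasi-Newton fallback on failure."""
    theta = np.asarray(theta0, dtype=float).copy()
    ll = eng.loglik(theta)
    if ll <= _SENTINEL:
        raise RuntimeError("infeasible starting values")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = eng.score(theta)
        gnorm = np.max(np.abs(grad))
        if gnorm < gtol * (1.0 + abs(ll)):
            converged = True
            break
        H = eng.fd_hessian(theta)
        try:
            step = linalg.solve(-H, grad, assume_a="sym")
            if not np.all(np.isfinite(step)) or grad @ step <= 0:
                raise linalg.LinAlgError("not an ascent direction")
        except linalg.LinAlgError:
            step = grad / max(1.0, gnorm)  # steepest ascent fallback
        # backtracking line search
        lam, ll_new = 1.0, _SENTINEL
        for _ in range(40):
            cand = theta + lam * step
            ll_new = eng.loglik(cand)
            if ll_new > ll - 1e-12:
                break
            lam *= 0.5
        else:
            break  # no improvement possible
        rel_step = np.max(np.abs(lam * step)) / (1.0 + np.max(np.abs(theta)))
        theta, ll = theta + lam * step, ll_new
        if rel_step < 1e-12:
            converged = np.max(np.abs(eng.score(theta))) < 1e-4 * (1.0 + abs(ll))
            break
    if not converged:
        # quasi-Newton fallback, still reporting observed information later
        res = optimize.minimize(
            lambda th: -eng.loglik(th), theta,
            jac=lambda th: -eng.score(th), method="BFGS",
            options={"maxiter": 500, "gtol": 1e-8},
        )
        if -res.fun > ll:
            theta, ll = res.x, -res.fun
        converged = np.max(np.abs(eng.score(theta))) < 1e-5 * (1.0 + abs(ll))
    return theta, ll, converged, it


def _pilot_weibull(data: SurvivalData, spec: ModelSpec, gtol, max_iter):
    """df=1 fit (Weibull AFT) used for knot placement and initialisation."""
    pilot_spec = ModelSpec(df=1, covariates=spec.covariates)
    knots, _ = _resolve_knots(data, pilot_spec)
    eng = _Engine(data, pilot_spec, knots, {})
    exposure = float(np.sum(data.t - data.t0))
    rate = max(data.n_events, 0.5) / exposure
    theta0 = np.concatenate([[np.log(rate), 1.0], np.zeros(eng.n_beta)])
    theta, ll, conv, _ = _newton(eng, theta0, gtol, max_iter)
    return theta, knots, eng


def fit(data: SurvivalData, spec: ModelSpec, gtol: float = 1e-8,
        max_iter: int = 200, bic_n: str = "events") -> FittedAFT:
    """Maximum-likelihood fit of the flexible parametric AFT model.

    Knot placement uses accelerated times from a Weibull pilot fit: the df=1
    model is fitted first, its beta gives phi-hat, baseline knots go on the
    quantiles of uncensored log(t * phi-hat), and are then frozen for the
    spline fit.  Initialisation starts the spline at the pilot's Weibull
    solution (higher-order gamma terms zero), which the spline model nests.

    ``bic_n``: "events" (default, standard in flexible parametric survival
    practice) or "n" for the total sample size in the BIC penalty.
    """
    if data.n_events == 0:
        raise ValueError("cannot fit: no events")
    theta_pilot, pilot_knots, _ = _pilot_weibull(data, spec, gtol, max_iter)
    g0, g1 = theta_pilot[0], theta_pilot[1]
    beta_pilot = theta_pilot[2:]
    if spec.df == 1 and not spec.tvc and spec.knots is None:
        knots, tvc_knots = pilot_knots, {}
        eng = _Engine(data, spec, knots, tvc_knots)
        theta, ll, converged, n_iter = _newton(eng, theta_pilot, gtol, max_iter)
    else:
        phi_hat = np.exp(-(np.asarray(data.X[list(spec.covariates)], dtype=float)
                           @ beta_pilot)) if spec.covariates else np.ones(data.n)
        knots, tvc_knots = _resolve_knots(data, spec, phi_hat=phi_hat)
        eng = _Engine(data, spec, knots, tvc_knots)
        # orthogonalise the baseline basis at the pilot's accelerated event
        # times for optimizer conditioning; gamma is reported on the raw scale
        ev = data.delta == 1.0
        u_ev = np.log(data.t[ev]) + np.log(phi_hat[ev])
        M = eng._aug(u_ev, 0)
        try:
            R = np.linalg.qr(M / np.sqrt(u_ev.size), mode="r")
            signs = np.sign(np.diag(R))
            signs[signs == 0] = 1.0
            T = linalg.solve_triangular(R * signs[:, None], np.eye(R.shape[0]))
            if not np.all(np.isfinite(T)):
                raise linalg.LinAlgError
        except linalg.LinAlgError:
            T = np.eye(eng.n_gamma)
        eng.set_transform(T)
        gamma_raw0 = np.concatenate([[g0, g1], np.zeros(knots.df - 1)])
        theta0 = np.concatenate([
            np.linalg.solve(T, gamma_raw0), beta_pilot,
            np.zeros(sum(eng.tvc_sizes)),
        ])
        theta, ll, converged, n_iter = _newton(eng, theta0, gtol, max_iter)

    H = eng.fd_hessian(theta)
    info = -H
    try:
        vcov = linalg.inv(info)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
            raise linalg.LinAlgError
    except linalg.LinAlgError:
        raise linalg.LinAlgError("information matrix singular") from None

    # map coefficients and covariance back to the raw truncated-power scale
    J = np.eye(eng.n_params)
    J[: eng.n_gamma, : eng.n_gamma] = eng.T
    theta = J @ theta
    vcov = J @ vcov @ J.T
    eng.set_transform(None)
    g, b, gp = eng.unpack(theta)
    p = theta.size
    n_bic = data.n_events if bic_n == "events" else data.n
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + np.log(max(n_bic, 1)) * p
    # diagnostic: fraction of a time grid where the fitted baseline slope <= 0
    grid = np.exp(np.linspace(knots.k_min, knots.k_max, 101))
    sp_grid = _s_prime(np.log(grid), g, knots)
    neg_frac = float(np.mean(sp_grid <= 0))
    return FittedAFT(
        gamma=g, beta=b,
        tvc_gamma={t.covariate: gv for t, gv in zip(spec.tvc, gp)},
        vcov=vcov, loglik=float(ll), aic=float(aic), bic=float(bic),
        converged=bool(converged), n_events=data.n_events, n=data.n,
        knots=knots, tvc_knots=tvc_knots, spec=spec,
        param_names=eng.param_names(), n_iter=n_iter,
        neg_sprime_fraction=neg_frac,
    )


def information_criteria(loglik_value: float, n_params: int, n: int):
    """(AIC, BIC) for a maximised log likelihood with ``n_params`` free parameters."""
    aic = -2.0 * loglik_value + 2.0 * n_params
    bic = -2.0 * loglik_value + n_params * np.log(n)
    return float(aic), float(bic)
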