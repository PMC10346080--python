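"""Restricted cubic splines in truncated power form.

The baseline of the flexible parametric AFT model is a natural (restricted)
cubic spline ``s(u) = gamma_0 + gamma_1 v_1(u) + ... + gamma_df v_df(u)``
evaluated on the log accelerated-time scale ``u = log(t * phi)``.  The basis
is the classical truncated power form

    v_1(u) = u
    v_j(u) = (u - k_j)^3_+ - lam_j (u - k_min)^3_+ - (1 - lam_j)(u - k_max)^3_+

with ``lam_j = (k_max - k_j) / (k_max - k_min)`` for each interior knot
``k_j``.  The restriction makes ``s`` exactly linear outside the boundary
knots, which stabilises extrapolation of the log cumulative hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotVector", "place_knots", "rcs_basis", "rcs_deriv", "rcs_deriv2"]


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing knots on a log-time scale.

    ``df`` (the number of basis columns, excluding the intercept) is always
    ``len(knots) - 1``; ``df == 1`` means boundary knots only and the basis
    degenerates to the identity map ``u -> u`` (a Weibull baseline).
    """

    knots: np.ndarray
    df: int = field(init=False)

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 1 or k.size < 2:
            raise ValueError("need at least 2 knots (the boundaries)")
        if not np.all(np.diff(k) > 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", k)
        object.__setattr__(self, "df", k.size - 1)

    @property
    def k_min(self) -> float:
        return float(self.knots[0])

    @property
    def k_max(self) -> float:
        return float(self.knots[-1])

    @property
    def interior(self) -> np.ndarray:
        return self.knots[1:-1]


def place_knots(log_event_times: np.ndarray, df: int) -> KnotVector:
    """Quantile-based knot placement on uncensored log event times.

    Boundary knots sit at the min and max of the input; the ``df - 1``
    interior knots sit at equally spaced quantiles (df=3 -> 1/3, 2/3),
    computed with the linear-interpolation quantile estimator.
    """
    u = np.asarray(log_event_times, dtype=float)
    if u.size == 0:
        raise ValueError("no uncensored event times to place knots on")
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(u)
    if df + 1 > distinct.size:
        raise ValueError("insufficient distinct event times for requested df")
    probs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(u, probs)  # linear interpolation rule
    uniq = np.unique(knots)
    if uniq.size < knots.size:
        warnings.warn(
            "duplicate knots collapsed; effective df reduced to "
            f"{uniq.size - 1}",
            stacklevel=2,
        )
        knots = uniq
    return KnotVector(knots)


def _pos3(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, 0.0) ** 3


def rcs_basis(u, kv: KnotVector) -> np.ndarray:
    """Basis matrix, shape ``(n, df)`` (scalar input gives shape ``(df,)``).

    Column 1 is ``u`` itself; remaining columns are the restricted cubic
    terms, one per interior knot.  No intercept column is included.
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.empty((u_arr.size, kv.df))
    out[:, 0] = u_arr
    if kv.df > 1:
        kmin, kmax = kv.k_min, kv.k_max
        span = kmax - kmin
        lo = _pos3(u_arr - kmin)
        hi = _pos3(u_arr - kmax)
        for j, kj in enumerate(kv.interior, start=1):
            lam = (kmax - kj) / span
            out[:, j] = _pos3(u_arr - kj) - lam * lo - (1.0 - lam) * hi
    return out[0] if np.isscalar(u) or np.ndim(u) == 0 else out


def rcs_deriv(u, kv: KnotVector) -> np.ndarray:
    """Analytic first derivative of each basis column with respect to ``u``."""
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.empty((u_arr.size, kv.df))
    out[:, 0] = 1.0
    if kv.df > 1:
        kmin, kmax = kv.k_min, kv.k_max
        span = kmax - kmin
        lo = 3.0 * np.where(u_arr > kmin, u_arr - kmin, 0.0) ** 2
        hi = 3.0 * np.where(u_arr > kmax, u_arr - kmax, 0.0) ** 2
        for j, kj in enumerate(kv.interior, start=1):
            lam = (kmax - kj) / span
            mid = 3.0 * np.where(u_arr > kj, u_arr - kj, 0.0) ** 2
            out[:, j] = mid - lam * lo - (1.0 - lam) * hi
    return out[0] if np.isscalar(u) or np.ndim(u) == 0 else out


def rcs_deriv2(u, kv: KnotVector) -> np.ndarray:
    """Second derivative of the basis; needed by the likelihood score."""
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.zeros((u_arr.size, kv.df))
    if kv.df > 1:
        kmin, kmax = kv.k_min, kv.k_max
        span = kmax - kmin
        lo = 6.0 * np.where(u_arr > kmin, u_arr - kmin, 0.0)
        hi = 6.0 * np.where(u_arr > kmax, u_arr - kmax, 0.0)
        for j, kj in enumerate(kv.interior, start=1):
            lam = (kmax - kj) / span
            mid = 6.0 * np.where(u_arr > kj, u_arr - kj, 0.0)
            out[:, j] = mid - lam * lo - (1.0 - lam) * hi
    return out[0] if np.isscalar(u) or np.ndim(u) == 0 else out
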