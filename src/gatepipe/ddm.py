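"""Drift-diffusion model core: simulation and first-passage-time likelihood.

The two-boundary drift-diffusion model (DDM) describes a noisy evidence
variable starting at ``z_rel * a`` that drifts at rate ``v`` (unit diffusion
coefficient) until it is absorbed at 0 (lower boundary) or ``a`` (upper
boundary); observed response time adds a non-decision offset ``t``.  Under
accuracy coding the upper boundary is the correct response.

Two routes to the same process are provided and cross-validated against each
other in the test suite:

* :func:`simulate` — Euler–Maruyama paths with Brownian-bridge crossing
  detection inside each step (without it, first-passage times are biased
  upward by O(sqrt(dt))).
* :func:`wfpt_density` — the exact first-passage-time density evaluated by
  whichever of the short-time and long-time series representations needs
  fewer terms for the requested error tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DDMParams",
    "simulate",
    "wfpt_density",
    "wfpt_logpdf",
    "loglik",
    "upper_probability",
    "predicted_cdf",
]


@dataclass(frozen=True)
class DDMParams:
    """Boundary separation ``a``, drift ``v``, non-decision time ``t`` (s),
    relative start point ``z_rel`` (0.5 = unbiased)."""

    a: float
    v: float
    t: float
    z_rel: float = 0.5

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if self.t < 0:
            raise ValueError(f"non-decision time t must be >= 0, got {self.t}")
        if not 0 < self.z_rel < 1:
            raise ValueError(f"z_rel must lie strictly in (0, 1), got {self.z_rel}")


def upper_probability(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    a, v, w = params.a, params.v, params.z_rel
    if v == 0.0:
        return w
    # P(upper) = (1 - exp(-2 v z)) / (1 - exp(-2 v a)), z = w * a
    num = -np.expm1(-2.0 * v * w * a)
    den = -np.expm1(-2.0 * v * a)
    return float(num / den)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _simulate_kernel(a, v, z0, dt, n, max_steps, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    rts = np.empty(n)
    upper = np.empty(n, dtype=np.bool_)
    done = np.empty(n, dtype=np.bool_)
    sqdt = np.sqrt(dt)
    for i in range(n):
        x = z0
        absorbed = False
        for k in range(max_steps):
            xn = x + v * dt + sqdt * np.random.standard_normal()
            if xn >= a:
                rts[i] = (k + 1) * dt
                upper[i] = True
                absorbed = True
                break
            if xn <= 0.0:
                rts[i] = (k + 1) * dt
                upper[i] = False
                absorbed = True
                break
            # Brownian-bridge probability of an unobserved within-step crossing
            p_up = np.exp(-2.0 * (a - x) * (a - xn) / dt)
            if np.random.random() < p_up:
                rts[i] = (k + 1) * dt
                upper[i] = True
                absorbed = True
                break
            p_lo = np.exp(-2.0 * x * xn / dt)
            if np.random.random() < p_lo:
                rts[i] = (k + 1) * dt
                upper[i] = False
                absorbed = True
                break
            x = xn
        done[i] = absorbed
        if not absorbed:
            rts[i] = np.nan
            upper[i] = False
    return rts, upper, done


def simulate(
    params: DDMParams,
    n: int,
    dt: float = 1e-3,
    seed: int | None = None,
    max_time: float = 20.0,
) -> pd.DataFrame:
    """Sample ``n`` (choice, rt) pairs from the DDM.

    Returns a DataFrame with columns ``choice`` (``"upper"``/``"lower"``) and
    ``rt`` (seconds, including non-decision time).  Paths not absorbed within
    ``max_time`` of decision time come back as ``choice="omission"`` with
    NaN rt; at sane parameters this is vanishingly rare.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    seed = int(np.random.default_rng(seed).integers(2**31 - 1)) if seed is None else int(seed)
    max_steps = int(np.ceil(max_time / dt))
    rts, upper, done = _simulate_kernel(
        params.a, params.v, params.z_rel * params.a, dt, int(n), max_steps, seed
    )
    choice = np.where(upper, "upper", "lower").astype(object)
    choice[~done] = "omission"
    rt = np.where(done, rts + params.t, np.nan)
    return pd.DataFrame({"choice": choice, "rt": rt})


# ---------------------------------------------------------------------------
# first-passage-time density
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fpt_scaled(tt, w, eps):  # pragma: no cover - numba
    """Density of first passage through 0 at scaled time ``tt`` for a
    zero-drift unit process between 0 and 1 starting at ``w``.

    Chooses between the short-time and long-time series by whichever needs
    fewer terms to bound the truncation error below ``eps``.
    """
    # terms needed by the short-time expansion
    if 2.0 * np.sqrt(2.0 * np.pi * tt) * eps < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * tt)))
        ks = max(ks, np.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    # terms needed by the long-time expansion
    if np.pi * tt * eps < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * eps) / (np.pi * np.pi * tt))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(tt)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tt))

    if ks < kl:
        K = int(np.ceil(ks))
        s = 0.0
        for k in range(-((K - 1) // 2), K // 2 + 1):
            s += (w + 2.0 * k) * np.exp(-((w + 2.0 * k) ** 2) / (2.0 * tt))
        return s / np.sqrt(2.0 * np.pi * tt**3)
    K = int(np.ceil(kl))
    s = 0.0
    for k in range(1, K + 1):
        s += k * np.exp(-(k * k) * (np.pi * np.pi) * tt / 2.0) * np.sin(k * np.pi * w)
    return s * np.pi


@njit(cache=True)
def _wfpt_logpdf_lower(rt, v, a, w, t0, eps):  # pragma: no cover - numba
    """Log density of hitting the LOWER boundary at observed time ``rt``."""
    tdec = rt - t0
    if tdec <= 0.0:
        return -np.inf
    tt = tdec / (a * a)
    f = _fpt_scaled(tt, w, eps)
    if f <= 0.0:
        return -np.inf
    return np.log(f) - np.log(a * a) - v * a * w - v * v * tdec / 2.0


@njit(cache=True)
def _loglik_kernel(rts, is_upper, a, v, t0, w, eps):  # pragma: no cover - numba
    total = 0.0
    for i in range(rts.shape[0]):
        if is_upper[i]:
            ll = _wfpt_logpdf_lower(rts[i], -v, a, 1.0 - w, t0, eps)
        else:
            ll = _wfpt_logpdf_lower(rts[i], v, a, w, t0, eps)
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


def wfpt_density(
    rt, params: DDMParams, boundary: str = "lower", err_tol: float = 1e-7
):
    """First-passage-time density at the named boundary.

    ``rt`` may be a scalar or array of observed times (seconds, including
    non-decision time); the density is 0 for ``rt <= t``.  The truncation of
    the series representation guarantees an absolute error below ``err_tol``
    on the scaled density.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    if err_tol <= 0:
        raise ValueError("err_tol must be positive")
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    if boundary == "upper":
        v, w = -params.v, 1.0 - params.z_rel
    else:
        v, w = params.v, params.z_rel
    out = np.empty(rt_arr.shape)
    for i, r in enumerate(rt_arr.ravel()):
        lp = _wfpt_logpdf_lower(r, v, params.a, w, params.t, err_tol)
        out.ravel()[i] = 0.0 if lp == -np.inf else np.exp(lp)
    return out[0] if np.isscalar(rt) or np.ndim(rt) == 0 else out


def wfpt_logpdf(rts: np.ndarray, is_upper: np.ndarray, params: DDMParams,
                err_tol: float = 1e-7) -> np.ndarray:
    """Per-observation log density (vectorized; -inf where rt <= t)."""
    rts = np.asarray(rts, dtype=float)
    is_upper = np.asarray(is_upper, dtype=bool)
    out = np.empty(rts.shape)
    for i in range(rts.size):
        if is_upper.ravel()[i]:
            out.ravel()[i] = _wfpt_logpdf_lower(
                rts.ravel()[i], -params.v, params.a, 1.0 - params.z_rel, params.t, err_tol
            )
        else:
            out.ravel()[i] = _wfpt_logpdf_lower(
                rts.ravel()[i], params.v, params.a, params.z_rel, params.t, err_tol
            )
    return out


def loglik(samples: pd.DataFrame, params: DDMParams, err_tol: float = 1e-7) -> float:
    """Joint log-likelihood of a (choice, rt) sample table; -inf if any
    observation is impossible under the parameters (rt <= t)."""
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    rts = samples["rt"].to_numpy(dtype=float)
    is_upper = (samples["choice"] == "upper").to_numpy()
    return float(
        _loglik_kernel(rts, is_upper, params.a, params.v, params.t, params.z_rel, err_tol)
    )


def predicted_cdf(params: DDMParams, boundary: str, t_max: float = 10.0,
                  n_grid: int = 4000) -> tuple[np.ndarray, np.ndarray]:
    """Defective CDF of RT at one boundary, by quadrature of the density.

    Returns ``(grid, cdf)``; ``cdf`` converges to the boundary's absorption
    probability as ``t_max`` grows.
    """
    from scipy.integrate import cumulative_trapezoid

    grid = np.linspace(params.t, params.t + t_max, n_grid)
    dens = wfpt_density(grid, params, boundary=boundary)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(dens, grid)])
    return grid, cdf
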