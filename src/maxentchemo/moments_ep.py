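"""Expectation Propagation moments of tilted distributions on flux polytopes.

The target density is P(v) proportional to exp(beta_prime * z(v)) on
{E v = d, l <= v <= u}. Each box indicator is approximated by a univariate
Gaussian site; since z is affine in v, the tilt is an exactly
Gaussian-compatible linear factor and introduces no moment-matching error
of its own. Sites are refined sequentially in a fixed order (deterministic)
with damping, and the reported per-variable moments are those of the final
tilted (truncated) marginals, which lie strictly inside the bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq, null_space
from scipy.optimize import linprog
from scipy.special import erfcx, ndtr

from .model_core import FluxPolytope, InfeasiblePolytopeError
from .moments_exact import MomentResult

__all__ = ["EPOptions", "EPState", "truncnorm_moments", "ep_moments"]

_SQRT2 = math.sqrt(2.0)
_SQRT_2_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class EPOptions:
    damping: float = 0.9  # fraction of the old site kept per update
    tol: float = 1e-6  # max abs change of (scaled) means and variances
    max_iter: int = 2000
    var_min: float = 1e-50  # clip for site / tilted variances
    var_max: float = 1e50
    tighten_bounds: bool = True  # replace infinite bounds by the LP box

    def __post_init__(self) -> None:
        if not (0 <= self.damping < 1):
            raise ValueError("damping must be in [0, 1)")
        if not self.tol > 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class EPState:
    site_precision: np.ndarray
    site_precision_mean: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    n_iter: int = 0
    max_change_trace: list[float] = field(default_factory=list)


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)


def _onesided(alpha: float) -> tuple[float, float]:
    """Standardized mean and variance of N(0,1) truncated to [alpha, inf)."""
    if alpha > 100.0:
        # asymptotic series of the Mills-ratio correction r = h - alpha
        ia = 1.0 / alpha
        ia2 = ia * ia
        r = ia * (1.0 - 2.0 * ia2 + 10.0 * ia2**2 - 74.0 * ia2**3)
        var = ia2 * (1.0 - 6.0 * ia2 + 50.0 * ia2**2 - 518.0 * ia2**3)
        return alpha + r, var
    h = _SQRT_2_PI / erfcx(alpha / _SQRT2)
    r = h - alpha
    return h, max(1.0 - h * r, 1e-300)


def truncnorm_moments(
    mu: float, sigma2: float, a: float, b: float
) -> tuple[float, float]:
    """Mean and variance of Gaussian(mu, sigma2) truncated to [a, b].

    Stable in far-tail regimes via scaled complementary error functions
    (plus asymptotic / narrow-interval expansions where direct evaluation
    cancels catastrophically).
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    if not a < b:
        raise ValueError("require a < b")
    sigma = math.sqrt(sigma2)
    lo = (a - mu) / sigma if math.isfinite(a) else -math.inf
    hi = (b - mu) / sigma if math.isfinite(b) else math.inf

    if lo == -math.inf and hi == math.inf:
        return mu, sigma2
    if hi == math.inf:
        m, v = _onesided(lo)
        return mu + sigma * m, sigma2 * v
    if lo == -math.inf:
        m, v = _onesided(-hi)
        return mu - sigma * m, sigma2 * v

    # reflect so the interval sits in the right half-plane
    flip = lo + hi < 0
    if flip:
        lo, hi = -hi, -lo

    width = hi - lo
    if width < 1e-5:
        # nearly uniform on a narrow slab; linear-density correction
        mid = 0.5 * (lo + hi)
        m = mid - mid * width**2 / 12.0
        v = width**2 / 12.0
    elif lo >= 0:
        delta = 0.5 * (hi - lo) * (hi + lo)
        if delta > 745.0:
            m, v = _onesided(lo)
        else:
            emd = math.exp(-delta)
            denom = erfcx(lo / _SQRT2) - emd * erfcx(hi / _SQRT2)
            h1 = _SQRT_2_PI * (-math.expm1(-delta)) / denom
            h2 = _SQRT_2_PI * (lo - hi * emd) / denom
            m = h1
            v = max(1.0 + h2 - h1 * h1, 1e-300)
    else:
        # straddling zero: direct formulas are well conditioned
        Z = ndtr(hi) - ndtr(lo)
        pa, pb = _phi(lo), _phi(hi)
        h1 = (pa - pb) / Z
        h2 = (lo * pa - hi * pb) / Z
        m = h1
        v = max(1.0 + h2 - h1 * h1, 1e-300)

    if flip:
        m = -m
    return mu + sigma * m, sigma2 * v


# ---------------------------------------------------------------------------
# EP proper
# ---------------------------------------------------------------------------

def _bounding_box(polytope: FluxPolytope) -> tuple[np.ndarray, np.ndarray]:
    """Tight per-variable bounds over the polytope (2 LPs per open bound)."""
    lb = polytope.lb.copy()
    ub = polytope.ub.copy()
    bounds = list(zip(polytope.lb, polytope.ub))
    A_eq = polytope.E if polytope.E.shape[0] else None
    b_eq = polytope.d if polytope.E.shape[0] else None
    for n in range(polytope.n_vars):
        for sign, arr in ((1.0, lb), (-1.0, ub)):
            if math.isfinite(arr[n]):
                continue
            c = np.zeros(polytope.n_vars)
            c[n] = sign
            res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                          method="highs")
            if res.status == 2:
                raise InfeasiblePolytopeError("polytope is empty")
            if res.status != 0:
                raise ValueError(
                    f"variable {polytope.var_names[n]} is unbounded; EP "
                    "requires a bounded polytope"
                )
            arr[n] = sign * res.fun
    return lb, ub


def ep_moments(
    polytope: FluxPolytope,
    beta_prime: float,
    options: EPOptions | None = None,
) -> MomentResult:
    """EP approximation of the moments of exp(beta_prime * z) on the polytope."""
    opt = options or EPOptions()
    if beta_prime < 0:
        raise ValueError("beta_prime must be non-negative")
    n = polytope.n_vars

    lb, ub = (polytope.lb.copy(), polytope.ub.copy())
    if opt.tighten_bounds and (np.any(~np.isfinite(lb)) or np.any(~np.isfinite(ub))):
        lb, ub = _bounding_box(polytope)
    if np.any(~np.isfinite(lb)) or np.any(~np.isfinite(ub)):
        raise ValueError("EP requires finite (or tightenable) bounds")

    # rescale each variable by its bound width to O(1)
    width = np.maximum(ub - lb, 1e-12)
    E = polytope.E * width if polytope.E.shape[0] else polytope.E
    d = polytope.d
    slb, sub = lb / width, ub / width
    stilt = polytope.tilt * width

    fixed = sub - slb <= 1e-12 * np.maximum(1.0, np.abs(sub))
    free = ~fixed
    Eaug = E
    daug = d
    if np.any(fixed):
        pin = np.eye(n)[fixed]
        Eaug = np.vstack([E, pin]) if E.shape[0] else pin
        daug = np.concatenate([d, 0.5 * (slb + sub)[fixed]])

    if Eaug.shape[0]:
        x0, *_ = lstsq(Eaug, daug)
        if np.max(np.abs(Eaug @ x0 - daug)) > 1e-7 * max(1.0, float(np.max(np.abs(daug)))):
            raise InfeasiblePolytopeError("equality system is inconsistent")
        B = null_space(Eaug)
        if B.size == 0:
            B = np.zeros((n, 0))
    else:
        x0 = np.zeros(n)
        B = np.eye(n)
    m_dim = B.shape[1]

    if m_dim == 0:
        mean = x0 * width
        if np.any(mean < lb - 1e-7) or np.any(mean > ub + 1e-7):
            raise InfeasiblePolytopeError("pinned point violates bounds")
        return MomentResult(
            var_names=list(polytope.var_names), mean=mean, var=np.zeros(n),
            z_mean=polytope.z_of(mean), z_var=0.0, method="ep",
            converged=True, n_iter=0, error_estimate=0.0,
        )

    rho = np.where(free, 1.0, 0.0)
    gamma = np.zeros(n)
    tilt_lin = beta_prime * stilt

    state = EPState(site_precision=rho, site_precision_mean=gamma,
                    mean=np.zeros(n), var=np.ones(n))
    jitter = 1e-12
    order = np.nonzero(free)[0]
    prev_mean = np.full(n, np.nan)
    prev_var = np.full(n, np.nan)
    converged = False
    max_change = math.inf

    for it in range(opt.max_iter):
        Lam = (B.T * rho) @ B + jitter * np.eye(m_dim)
        h = B.T @ (gamma + tilt_lin - rho * x0)
        Sigma = np.linalg.inv(Lam)
        m_y = Sigma @ h

        for idx in order:
            b = B[idx]
            Sb = Sigma @ b
            s = float(b @ Sb)
            if s <= 0:
                continue
            mu = x0[idx] + float(b @ m_y)
            p_cav = 1.0 / s - rho[idx]
            p_cav = max(p_cav, 1.0 / opt.var_max)
            h_cav = mu / s - gamma[idx]
            mu_c = h_cav / p_cav
            var_c = min(1.0 / p_cav, opt.var_max)
            m_t, v_t = truncnorm_moments(mu_c, var_c, slb[idx], sub[idx])
            v_t = min(max(v_t, opt.var_min), opt.var_max)
            rho_star = 1.0 / v_t - p_cav
            gamma_star = m_t / v_t - h_cav
            rho_new = opt.damping * rho[idx] + (1 - opt.damping) * rho_star
            gamma_new = opt.damping * gamma[idx] + (1 - opt.damping) * gamma_star
            rho_new = min(max(rho_new, 0.0), 1.0 / opt.var_min)
            d_rho = rho_new - rho[idx]
            d_gamma = gamma_new - gamma[idx]
            denom = 1.0 + d_rho * s
            if denom <= 1e-14:
                continue
            Sigma -= np.outer(Sb, Sb) * (d_rho / denom)
            h += (d_gamma - d_rho * x0[idx]) * b
            m_y = Sigma @ h
            rho[idx] = rho_new
            gamma[idx] = gamma_new

        mean_s = x0 + B @ m_y
        var_s = np.einsum("ij,jk,ik->i", B, Sigma, B)
        max_change = float(
            np.nanmax(np.abs(mean_s - prev_mean).tolist()
                      + np.abs(var_s - prev_var).tolist())
        ) if it else math.inf
        state.max_change_trace.append(max_change)
        prev_mean, prev_var = mean_s, var_s
        state.n_iter = it + 1
        if max_change < opt.tol:
            converged = True
            break

    # tilted (truncated) marginal moments from the final approximation
    mean_out = np.empty(n)
    var_out = np.empty(n)
    for idx in range(n):
        if fixed[idx]:
            mean_out[idx] = 0.5 * (slb[idx] + sub[idx])
            var_out[idx] = 0.0
            continue
        b = B[idx]
        s = float(b @ Sigma @ b)
        mu = x0[idx] + float(b @ m_y)
        if s <= 0:
            mean_out[idx] = min(max(mu, slb[idx]), sub[idx])
            var_out[idx] = 0.0
            continue
        p_cav = max(1.0 / s - rho[idx], 1.0 / opt.var_max)
        h_cav = mu / s - gamma[idx]
        m_t, v_t = truncnorm_moments(h_cav / p_cav, min(1.0 / p_cav, opt.var_max),
                                     slb[idx], sub[idx])
        mean_out[idx] = m_t
        var_out[idx] = max(v_t, 0.0)

    state.mean = mean_out * width
    state.var = var_out * width**2
    t_red = B.T @ stilt
    z_var = float(t_red @ Sigma @ t_red)
    z_mean = float(polytope.tilt @ state.mean) + polytope.z_offset

    return MomentResult(
        var_names=list(polytope.var_names),
        mean=state.mean,
        var=state.var,
        z_mean=z_mean,
        z_var=z_var,
        method="ep",
        converged=converged,
        n_iter=state.n_iter,
        error_estimate=max_change,
        meta={"options": opt, "state": state},
    )
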